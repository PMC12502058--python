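"""Shared fixtures: the standard synthetic scenario, fitted pixel map, and
session-scoped trained models (full and holdout) reused across test modules."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from hicanno import annotate, hierarchy, image_mapper, model, preprocess, synthetic, train

GRID = 32
CHANNELS = 1
HOLDOUT = ("gdT",)


@pytest.fixture(scope="session")
def standard_data():
    return synthetic.generate(synthetic.standard_scenario())


@pytest.fixture(scope="session")
def query_data():
    """A fresh draw from the same generator, never used for training."""
    return synthetic.generate(synthetic.standard_scenario(seed=123))


@pytest.fixture(scope="session")
def hier(standard_data):
    return standard_data.scenario.hierarchy


@dataclass
class FittedScenario:
    data: synthetic.SyntheticDataset
    aligned: preprocess.ExpressionMatrix
    pmap: image_mapper.PixelMap
    images: np.ndarray
    base_idx: np.ndarray
    sub_idx: np.ndarray


def _fit(data, hier_used):
    ln = preprocess.lognormalize(data.matrix)
    panel = preprocess.select_hvgs(ln, data.matrix.n_genes)
    aligned, _ = preprocess.align_to_panel(ln, panel)
    pmap = image_mapper.fit_pixel_map(aligned, GRID, GRID, seed=0)
    images = image_mapper.render_batch(aligned, pmap, n_channels=CHANNELS)
    base_idx, sub_idx = hierarchy.encode_labels(
        hier_used, data.base_labels, data.sub_labels
    )
    return FittedScenario(data, aligned, pmap, images, base_idx, sub_idx)


@pytest.fixture(scope="session")
def fitted(standard_data, hier):
    return _fit(standard_data, hier)


@pytest.fixture(scope="session")
def trained(fitted, hier):
    """Classifier trained on the full standard scenario (all six subtypes)."""
    cfg = model.HierarchicalClassifierConfig(image_hw=(GRID, GRID), n_channels=CHANNELS)
    return train.train_model(
        fitted.images, fitted.base_idx, fitted.sub_idx, hier, cfg,
        train.TrainConfig(seed=0), pixel_map=fitted.pmap,
    )


@pytest.fixture(scope="session")
def query_annotations(trained, fitted, query_data):
    """Annotations of the fresh query by the fully trained model."""
    ln = preprocess.lognormalize(query_data.matrix)
    preds, report = annotate.annotate_cells(ln, trained.classifier, fitted.pmap)
    return preds, report


@pytest.fixture(scope="session")
def holdout_fitted(standard_data, hier):
    """Pixel map and images fitted on the scenario with one subtype held out."""
    hier_h = hier.drop_subtypes(HOLDOUT)
    return _fit(standard_data.without_subtypes(HOLDOUT), hier_h), hier_h


@pytest.fixture(scope="session")
def holdout_trained(holdout_fitted):
    """A small deep ensemble trained without the held-out subtype; ensemble-
    averaged probabilities carry the calibrated uncertainty that the
    rare-population score relies on."""
    fitted_h, hier_h = holdout_fitted
    cfg = model.HierarchicalClassifierConfig(image_hw=(GRID, GRID), n_channels=CHANNELS)
    return train.train_ensemble(
        fitted_h.images, fitted_h.base_idx, fitted_h.sub_idx, hier_h, cfg,
        train.TrainConfig(seed=0), n_members=3, pixel_map=fitted_h.pmap,
    )


@pytest.fixture(scope="session")
def holdout_annotations(holdout_trained, holdout_fitted, standard_data):
    """All standard-scenario cells (including the held-out subtype) annotated
    by the holdout-trained ensemble."""
    fitted_h, _ = holdout_fitted
    ln = preprocess.lognormalize(standard_data.matrix)
    preds, _ = annotate.annotate_cells(
        ln, [r.classifier for r in holdout_trained], fitted_h.pmap
    )
    is_novel = np.array([s == HOLDOUT[0] for s in standard_data.sub_labels])
    return preds, is_novel
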