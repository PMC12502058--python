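"""Attribution back-ends, gene fold-back, and marker recovery."""

import numpy as np
import pandas as pd
import pytest

from hicanno import ValidationError
from hicanno.annotate import predictions_frame
from hicanno.explain import (GeneImportanceTable, attribute, class_importance,
                             fold_to_genes, top_genes)
from hicanno.image_mapper import PixelMap

from conftest import CHANNELS


class LinearProbe:
    """Minimal model whose class score is w . pixel(0, 0): the only pixel
    with nonzero occlusion attribution by construction."""

    def __init__(self, w=2.5):
        self.w = w

    def class_score(self, images, level, class_index):
        return self.w * images[:, :, 0, 0].sum(axis=1)

    def class_score_input_grad(self, images, level, class_index):
        g = np.zeros_like(images)
        g[:, :, 0, 0] = self.w
        return g


class ConstantModel:
    def class_score(self, images, level, class_index):
        return np.full(images.shape[0], 3.0)

    def class_score_input_grad(self, images, level, class_index):
        return np.zeros_like(images)


def small_pmap():
    return PixelMap(
        grid_h=2, grid_w=2, gene_names=["gA", "gB", "gC"],
        rows=np.array([0, 0, 1]), cols=np.array([0, 1, 1]),
        per_gene_min=np.zeros(3), per_gene_max=np.ones(3),
        embedding_coords=np.zeros((3, 2)), projection_seed=0,
        projection_method="tsne",
    )


class TestOcclusion:
    def test_constant_model_all_zero(self):
        maps = attribute(ConstantModel(), np.random.default_rng(0).random((4, 1, 3, 3)),
                         "base", 0, method="occlusion", pixels="all")
        assert np.all(maps == 0)

    def test_linear_probe_only_corner_pixel(self):
        images = np.random.default_rng(1).random((3, 2, 4, 4))
        maps = attribute(LinearProbe(), images, "base", 0,
                         method="occlusion", pixels="all")
        corner = maps[:, 0, 0]
        expected = 2.5 * images[:, :, 0, 0].sum(axis=1)
        assert np.allclose(corner, expected)
        maps[:, 0, 0] = 0
        assert np.all(maps == 0)

    def test_matches_two_forward_pass_definition(self, trained, fitted):
        """Definitional oracle recomputed in the test: attribution at pixel p
        equals score(x) - score(x with p zeroed)."""
        clf = trained.classifier
        images = fitted.images[:3]
        maps = attribute(clf, images, "base", 0, method="occlusion", pixels="all")
        h, w = images.shape[2:]
        base = clf.class_score(images, "base", 0)
        rng = np.random.default_rng(2)
        for _ in range(25):  # spot-check a random subset of pixels
            r, c = int(rng.integers(h)), int(rng.integers(w))
            occ = images.copy()
            occ[:, :, r, c] = 0.0
            expected = base - clf.class_score(occ, "base", 0)
            assert np.allclose(maps[:, r, c], expected)

    def test_empty_cell_set_rejected(self):
        with pytest.raises(ValidationError):
            attribute(ConstantModel(), np.zeros((0, 1, 2, 2)), "base", 0,
                      method="occlusion", pixels="all")


class TestExpectedGradients:
    def test_linear_model_recovers_exact_attribution(self):
        # for a linear score, expected gradients equal w * (x - E[background])
        images = np.random.default_rng(3).random((4, 1, 3, 3))
        background = np.zeros((6, 1, 3, 3))
        maps = attribute(LinearProbe(), images, "base", 0,
                         method="expected_gradients", background=background,
                         n_samples=10, seed=0)
        assert np.allclose(maps[:, 0, 0], 2.5 * images[:, 0, 0, 0])
        maps[:, 0, 0] = 0
        assert np.all(np.abs(maps) < 1e-12)

    def test_deterministic_given_seed(self, trained, fitted):
        kw = dict(method="expected_gradients", background=fitted.images[:10],
                  n_samples=5, seed=4)
        a = attribute(trained.classifier, fitted.images[:2], "base", 0, **kw)
        b = attribute(trained.classifier, fitted.images[:2], "base", 0, **kw)
        assert np.array_equal(a, b)

    def test_background_required(self):
        with pytest.raises(ValidationError):
            attribute(ConstantModel(), np.zeros((1, 1, 2, 2)), "base", 0,
                      method="expected_gradients")


class TestFoldToGenes:
    def test_single_cell_reads_gene_pixel(self):
        pmap = small_pmap()
        maps = np.zeros((1, 2, 2))
        maps[0, 0, 0] = 0.7
        table = fold_to_genes(maps, pmap, "T", "base")
        row = table.frame.set_index("gene_name").loc["gA"]
        assert row["mean_abs_attribution"] == pytest.approx(0.7)

    def test_signed_and_absolute_means(self):
        pmap = small_pmap()
        maps = np.zeros((2, 2, 2))
        maps[0, 0, 1] = 0.5
        maps[1, 0, 1] = -0.5
        table = fold_to_genes(maps, pmap, "T", "base")
        row = table.frame.set_index("gene_name").loc["gB"]
        assert row["mean_abs_attribution"] == pytest.approx(0.5)
        assert row["mean_signed_attribution"] == pytest.approx(0.0)
        assert row["n_cells"] == 2

    def test_unassigned_pixels_ignored(self):
        pmap = small_pmap()
        maps = np.zeros((1, 2, 2))
        maps[0, 1, 0] = 9.0  # (1, 0) carries no gene
        table = fold_to_genes(maps, pmap, "T", "base")
        assert (table.frame["mean_abs_attribution"] == 0).all()

    def test_shape_mismatch(self):
        with pytest.raises(ValidationError):
            fold_to_genes(np.zeros((1, 3, 3)), small_pmap(), "T", "base")


class TestTopGenes:
    def _table(self):
        frame = pd.DataFrame({
            "class_name": "T", "level": "base",
            "gene_name": ["b", "a", "c"],
            "mean_abs_attribution": [0.5, 0.5, 0.1],
            "mean_signed_attribution": [0.5, -0.5, 0.1],
            "n_cells": 3,
        })
        return GeneImportanceTable(frame)

    def test_ties_break_by_name(self):
        assert top_genes(self._table(), "T", "base", 2) == ["a", "b"]

    def test_k_beyond_panel_returns_everything(self):
        assert top_genes(self._table(), "T", "base", 99) == ["a", "b", "c"]

    def test_unknown_class_lists_valid_names(self):
        with pytest.raises(ValidationError, match="known classes"):
            top_genes(self._table(), "B", "base", 2)


@pytest.fixture(scope="module")
def query_frame_and_images(query_annotations, query_data, fitted):
    from hicanno.image_mapper import render_batch
    from hicanno.preprocess import align_to_panel, lognormalize

    preds, _ = query_annotations
    frame = predictions_frame(preds)
    ln = lognormalize(query_data.matrix)
    aligned, _ = align_to_panel(ln, fitted.pmap.gene_names)
    images = render_batch(aligned, fitted.pmap, n_channels=CHANNELS)
    return frame, images


class TestMarkerRecovery:
    def test_subtype_markers_in_top_ten(self, trained, fitted, query_data,
                                        query_frame_and_images, hier):
        """Each subtype's planted 5-gene block must surface in its top-10
        occlusion importance list (at least 3 of 5)."""
        frame, images = query_frame_and_images
        for name in hier.subtype_names:
            table = class_importance(
                trained.classifier, images, frame, fitted.pmap, name, "subtype",
                method="occlusion", max_cells=30,
            )
            top10 = set(top_genes(table, name, "subtype", 10))
            markers = set(query_data.marker_map[("subtype", name)])
            assert len(top10 & markers) >= 3, name

    def test_lineage_markers_rank_high_for_base_class(self, trained, fitted,
                                                      query_data,
                                                      query_frame_and_images):
        """Shared lineage markers dominate the base-level importance, the
        lineage-shared vs subtype-specific pattern at testable scale."""
        frame, images = query_frame_and_images
        table = class_importance(
            trained.classifier, images, frame, fitted.pmap, "T cell", "base",
            method="occlusion", max_cells=30,
        )
        top10 = set(top_genes(table, "T cell", "base", 10))
        lineage = set(query_data.marker_map[("base", "T cell")])
        assert len(top10 & lineage) >= 3

    def test_no_cells_of_class_rejected(self, trained, fitted,
                                        query_frame_and_images):
        frame, images = query_frame_and_images
        empty = frame.copy()
        empty["sub_label"] = ""
        with pytest.raises(ValidationError, match="no cells"):
            class_importance(trained.classifier, images, empty, fitted.pmap,
                             "CD4 T", "subtype", method="occlusion")
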