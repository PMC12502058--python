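"""Per-gene attribution of classification decisions.

Attributions are computed in image space — one score per pixel for a chosen
class at a chosen level — and folded back to genes through the pixel map
(each gene reads the attribution at its own pixel; unassigned pixels are
ignored).  Per class, genes are summarized by the mean absolute and mean
signed attribution across that class's cells; signed values are kept
because depressed marker genes can be genuinely discriminative.

Two back-ends share the same output schema:

``occlusion``
    Definitional and model-agnostic: the attribution of a pixel is the drop
    in the class score when that pixel is zeroed,
    ``score(x) - score(x with pixel p zeroed)``.  Exact but one forward
    pass per pixel; the reference back-end.
``expected_gradients``
    A sampled Shapley-style estimate: gradients of the class score taken at
    random points on segments between the input and background (training)
    images, multiplied by the input-background difference and averaged.
    Much faster on large grids; seed-controlled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import ValidationError, spawn_rng
from .image_mapper import PixelMap
from .model import HierarchicalClassifier

DEFAULT_N_BACKGROUND = 50
DEFAULT_N_EG_SAMPLES = 25


def attribute(
    clf: HierarchicalClassifier,
    images: np.ndarray,
    level: str,
    class_index: int,
    method: str = "expected_gradients",
    background: np.ndarray | None = None,
    pmap: PixelMap | None = None,
    pixels: str = "assigned",
    n_samples: int = DEFAULT_N_EG_SAMPLES,
    seed: int = 0,
) -> np.ndarray:
    """Per-cell per-pixel attribution maps, channels summed.

    ``images``: (N, C, H, W) cells sharing the queried predicted class.
    Returns (N, H, W).  For occlusion, ``pixels='assigned'`` (requires
    ``pmap``) restricts the scan to gene-carrying pixels — attributions
    elsewhere are zero by construction for rendered images — while
    ``pixels='all'`` scans the full grid.  ``expected_gradients`` requires a
    ``background`` image stack.
    """
    images = np.asarray(images, dtype=np.float64)
    if images.ndim != 4 or images.shape[0] == 0:
        raise ValidationError("need a non-empty (N, C, H, W) image stack")
    if method == "occlusion":
        return _occlusion(clf, images, level, class_index, pmap, pixels)
    if method == "expected_gradients":
        if background is None:
            raise ValidationError("expected_gradients needs a background image stack")
        return _expected_gradients(
            clf, images, level, class_index, background, n_samples, seed
        )
    raise ValidationError(f"unknown attribution method {method!r}")


def _occlusion(clf, images, level, class_index, pmap, pixels) -> np.ndarray:
    n, _, h, w = images.shape
    base = clf.class_score(images, level, class_index)
    if pixels == "assigned":
        if pmap is None:
            raise ValidationError("pixels='assigned' requires the pixel map")
        coords = list(zip(pmap.rows.tolist(), pmap.cols.tolist()))
    elif pixels == "all":
        coords = [(r, c) for r in range(h) for c in range(w)]
    else:
        raise ValidationError("pixels must be 'assigned' or 'all'")
    out = np.zeros((n, h, w))
    for r, c in coords:
        occluded = images.copy()
        occluded[:, :, r, c] = 0.0
        out[:, r, c] = base - clf.class_score(occluded, level, class_index)
    return out


def _expected_gradients(
    clf, images, level, class_index, background, n_samples, seed
) -> np.ndarray:
    rng = spawn_rng(seed, "expected_gradients")
    background = np.asarray(background, dtype=np.float64)
    n = images.shape[0]
    acc = np.zeros_like(images)
    for _ in range(n_samples):
        ref = background[rng.integers(0, background.shape[0], size=n)]
        t = rng.random((n, 1, 1, 1))
        point = ref + t * (images - ref)
        grad = clf.class_score_input_grad(point, level, class_index)
        acc += grad * (images - ref)
    return (acc / n_samples).sum(axis=1)  # sum channels


@dataclass
class GeneImportanceTable:
    """Rows of (class_name, level, gene, mean |attr|, mean attr, n_cells)."""

    frame: pd.DataFrame

    COLUMNS = ("class_name", "level", "gene_name",
               "mean_abs_attribution", "mean_signed_attribution", "n_cells")

    def __post_init__(self):
        missing = set(self.COLUMNS) - set(self.frame.columns)
        if missing:
            raise ValidationError(f"importance table missing columns {sorted(missing)}")

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GeneImportanceTable":
        return cls(pd.read_csv(path, sep="\t"))

    @classmethod
    def concat(cls, tables: list["GeneImportanceTable"]) -> "GeneImportanceTable":
        return cls(pd.concat([t.frame for t in tables], ignore_index=True))


def fold_to_genes(
    maps: np.ndarray, pmap: PixelMap, class_name: str, level: str
) -> GeneImportanceTable:
    """Read each gene's attribution at its pixel and average across cells."""
    maps = np.asarray(maps, dtype=np.float64)
    if maps.ndim != 3 or maps.shape[1:] != (pmap.grid_h, pmap.grid_w):
        raise ValidationError(
            f"attribution maps of shape {maps.shape} do not match the "
            f"{pmap.grid_h}x{pmap.grid_w} grid"
        )
    per_gene = maps[:, pmap.rows, pmap.cols]  # (n_cells, n_genes)
    frame = pd.DataFrame(
        {
            "class_name": class_name,
            "level": level,
            "gene_name": pmap.gene_names,
            "mean_abs_attribution": np.abs(per_gene).mean(axis=0),
            "mean_signed_attribution": per_gene.mean(axis=0),
            "n_cells": maps.shape[0],
        }
    )
    return GeneImportanceTable(frame)


def top_genes(
    table: GeneImportanceTable, class_name: str, level: str, k: int
) -> list[str]:
    """Top-k genes of one class by mean absolute attribution, ties by name."""
    sel = table.frame[
        (table.frame["class_name"] == class_name) & (table.frame["level"] == level)
    ]
    if sel.empty:
        known = sorted(table.frame["class_name"].unique())
        raise ValidationError(
            f"class {class_name!r} at level {level!r} not in table; "
            f"known classes: {known}"
        )
    ranked = sel.sort_values(
        ["mean_abs_attribution", "gene_name"], ascending=[False, True],
        kind="mergesort",
    )
    return ranked["gene_name"].head(max(k, 0)).tolist()


def class_importance(
    clf: HierarchicalClassifier,
    images: np.ndarray,
    predictions: pd.DataFrame,
    pmap: PixelMap,
    class_name: str,
    level: str,
    method: str = "expected_gradients",
    background: np.ndarray | None = None,
    max_cells: int = 60,
    seed: int = 0,
) -> GeneImportanceTable:
    """End-to-end importance for one class: select its predicted cells,
    attribute, and fold back to genes.  ``predictions`` is the per-cell
    annotation frame; at most ``max_cells`` cells are used (seeded sample).
    """
    if level == "base":
        mask = predictions["base_label"].to_numpy() == class_name
        class_index = clf.hier.base_index(class_name)
    elif level == "subtype":
        mask = predictions["sub_label"].to_numpy() == class_name
        class_index = clf.hier.subtype_index(class_name)
    else:
        raise ValidationError(f"level must be 'base' or 'subtype', got {level!r}")
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValidationError(f"no cells predicted as {class_name!r}")
    if idx.size > max_cells:
        idx = spawn_rng(seed, f"cells:{class_name}").choice(
            idx, size=max_cells, replace=False
        )
    maps = attribute(
        clf, images[idx], level, class_index, method=method,
        background=background, pmap=pmap, seed=seed,
    )
    return fold_to_genes(maps, pmap, class_name, level)
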