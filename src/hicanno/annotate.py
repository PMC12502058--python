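"""Apply a trained checkpoint to query data.

The query matrix is aligned to the model's gene panel (missing genes
zero-filled, coverage reported), rendered through the fitted pixel map,
and classified hierarchically with probability masking.  Each cell also
receives a *rare-population score*: the gap between its best base-type
probability and its best masked-subtype probability.  Cells confidently
placed in a lineage but matching none of its trained subtypes — the
signature of a population absent from the reference — score high, and can
be flagged with a pair of thresholds on base confidence and score.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import ValidationError
from .hierarchy import CellTypeHierarchy
from .image_mapper import PixelMap, render_batch
from .model import HierarchicalClassifier, HierarchicalPrediction, mask_subtype_probs
from .preprocess import CoverageReport, ExpressionMatrix, align_to_panel

logger = logging.getLogger(__name__)

DEFAULT_TAU_BASE = 0.8
DEFAULT_TAU_SCORE = 0.4
DEFAULT_COVERAGE_FLOOR = 50.0  # percent


def rare_score(pred: HierarchicalPrediction) -> float:
    """max base probability minus max masked-subtype probability, in [-1, 1].

    Terminal-leaf predictions have no subtype uncertainty to measure and
    score 0 by convention.
    """
    if pred.sub_probs_masked.size == 0 or pred.sub_probs_masked.sum() == 0:
        return 0.0
    return float(pred.base_probs.max() - pred.sub_probs_masked.max())


def flag_novel(
    preds: list[HierarchicalPrediction],
    tau_base: float = DEFAULT_TAU_BASE,
    tau_score: float = DEFAULT_TAU_SCORE,
) -> np.ndarray:
    """Boolean flag per cell: confident lineage and large rare score."""
    for name, tau in (("tau_base", tau_base), ("tau_score", tau_score)):
        if not 0.0 <= tau <= 1.0:
            raise ValidationError(f"{name} must be in [0, 1], got {tau}")
    return np.array(
        [p.base_probs.max() >= tau_base and p.rare_score >= tau_score for p in preds]
    )


def predictions_from_probs(
    base_probs: np.ndarray,
    sub_probs_raw: np.ndarray,
    hier: CellTypeHierarchy,
    cell_ids: list[str],
) -> list[HierarchicalPrediction]:
    """Assemble per-cell hierarchical predictions from raw probabilities."""
    masked = mask_subtype_probs(base_probs, sub_probs_raw, hier)
    subtype_names = hier.subtype_names
    preds = []
    for i, cid in enumerate(cell_ids):
        b_star = int(np.argmax(base_probs[i]))
        base_label = hier.base_names[b_star]
        if hier.is_terminal(b_star) or masked[i].sum() == 0:
            sub_label = None
        else:
            sub_label = subtype_names[int(np.argmax(masked[i]))]
        p = HierarchicalPrediction(
            cell_id=cid,
            base_probs=base_probs[i],
            sub_probs_raw=sub_probs_raw[i],
            sub_probs_masked=masked[i],
            base_label=base_label,
            sub_label=sub_label,
        )
        p.rare_score = rare_score(p)
        preds.append(p)
    return preds


def annotate_cells(
    query: ExpressionMatrix,
    clf: HierarchicalClassifier | list[HierarchicalClassifier],
    pmap: PixelMap,
    coverage_floor_pct: float = DEFAULT_COVERAGE_FLOOR,
) -> tuple[list[HierarchicalPrediction], CoverageReport]:
    """Align, render and classify a query matrix.

    ``clf`` may be a single trained model or a list of ensemble members
    trained on the same hierarchy and pixel map; with an ensemble the
    predicted probabilities are averaged over members before masking, which
    yields the better-calibrated uncertainty that rare-population scoring
    relies on.  Emits a warning when gene coverage falls below the
    configured floor; zero coverage is an error (raised by the alignment
    step).
    """
    members = clf if isinstance(clf, (list, tuple)) else [clf]
    if not members:
        raise ValidationError("need at least one classifier")
    hier = members[0].hier
    for m in members:
        m.check_pixel_map(pmap)
        if m.hier.to_dict() != hier.to_dict():
            raise ValidationError("ensemble members disagree on the hierarchy")
    aligned, report = align_to_panel(query, pmap.gene_names)
    if report.coverage_pct < coverage_floor_pct:
        warnings.warn(
            f"query covers only {report.coverage_pct:.1f}% of the "
            f"{report.n_panel}-gene panel; predictions may degrade"
        )
    logger.info("gene coverage: %.1f%%", report.coverage_pct)
    images = render_batch(aligned, pmap, n_channels=members[0].cfg.n_channels)
    pairs = [m.predict_proba(images) for m in members]
    base_probs = np.mean([p[0] for p in pairs], axis=0)
    sub_probs = np.mean([p[1] for p in pairs], axis=0)
    preds = predictions_from_probs(base_probs, sub_probs, hier, aligned.cell_ids)
    return preds, report


def predictions_frame(
    preds: list[HierarchicalPrediction],
    tau_base: float = DEFAULT_TAU_BASE,
    tau_score: float = DEFAULT_TAU_SCORE,
) -> pd.DataFrame:
    """Per-cell annotation table (one row per cell)."""
    flags = flag_novel(preds, tau_base, tau_score)
    return pd.DataFrame(
        {
            "cell_id": [p.cell_id for p in preds],
            "base_label": [p.base_label for p in preds],
            "base_prob": [p.base_prob for p in preds],
            "sub_label": [p.sub_label if p.sub_label is not None else "" for p in preds],
            "sub_prob": [p.sub_prob for p in preds],
            "rare_score": [p.rare_score for p in preds],
            "novel_flag": flags,
        }
    )


def write_annotation(
    preds: list[HierarchicalPrediction],
    query: ExpressionMatrix,
    hier: CellTypeHierarchy,
    tsv_path: str | Path | None = None,
    h5ad_path: str | Path | None = None,
    tau_base: float = DEFAULT_TAU_BASE,
    tau_score: float = DEFAULT_TAU_SCORE,
) -> pd.DataFrame:
    """Write the annotation TSV and/or an AnnData container with obs columns
    and the full probability matrices as obsm arrays."""
    frame = predictions_frame(preds, tau_base, tau_score)
    if tsv_path is not None:
        frame.to_csv(tsv_path, sep="\t", index=False)
    if h5ad_path is not None:
        adata = query.to_anndata()
        for col in ("base_label", "base_prob", "sub_label", "sub_prob",
                    "rare_score", "novel_flag"):
            adata.obs[col] = frame[col].to_numpy()
        adata.obsm["base_probs"] = np.stack([p.base_probs for p in preds])
        if hier.K_sub:
            adata.obsm["sub_probs_raw"] = np.stack([p.sub_probs_raw for p in preds])
            adata.obsm["sub_probs_masked"] = np.stack([p.sub_probs_masked for p in preds])
        adata.uns["base_names"] = list(hier.base_names)
        adata.uns["subtype_names"] = list(hier.subtype_names)
        adata.write_h5ad(h5ad_path)
    return frame
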