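"""Expression-matrix container, normalization, HVG selection, panel alignment.

The modeling pipeline works on a fixed *gene panel*: the highly variable
genes selected on the reference data.  Query matrices are aligned to that
panel before rendering — genes the query lacks are filled with zero on the
log-normalized scale, and the fraction of panel genes the query does carry
is reported as the *gene coverage* percentage.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

from ._utils import ValidationError

RAW_COUNTS = "raw_counts"
LOGNORM = "lognorm"


@dataclass
class ExpressionMatrix:
    """Dense cells x genes matrix with names and a processing-stage tag."""

    values: np.ndarray  # (n_cells, n_genes), non-negative
    gene_names: list[str]
    cell_ids: list[str]
    layer_tag: str = RAW_COUNTS

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2D cells x genes array")
        n_cells, n_genes = self.values.shape
        if len(self.cell_ids) != n_cells or len(self.gene_names) != n_genes:
            raise ValidationError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.cell_ids)} cell ids / {len(self.gene_names)} gene names"
            )
        if len(set(self.gene_names)) != n_genes:
            raise ValidationError("gene names must be unique")
        if n_genes and self.values.size and float(self.values.min()) < 0:
            raise ValidationError("expression values must be non-negative")
        if self.layer_tag not in (RAW_COUNTS, LOGNORM):
            raise ValidationError(f"unknown layer tag {self.layer_tag!r}")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_anndata(self):
        import anndata as ad
        import pandas as pd

        adata = ad.AnnData(
            X=self.values.copy(),
            obs=pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id")),
            var=pd.DataFrame(index=pd.Index(self.gene_names, name="gene")),
        )
        adata.uns["layer_tag"] = self.layer_tag
        return adata

    @classmethod
    def from_anndata(cls, adata, layer_tag: str | None = None) -> "ExpressionMatrix":
        import scipy.sparse as sp

        X = adata.X
        if sp.issparse(X):
            X = X.toarray()
        tag = layer_tag or adata.uns.get("layer_tag", RAW_COUNTS)
        return cls(
            values=np.asarray(X, dtype=np.float64),
            gene_names=[str(g) for g in adata.var_names],
            cell_ids=[str(c) for c in adata.obs_names],
            layer_tag=tag,
        )


#: pluggable batch-correction hook applied to the lognorm matrix before HVG
#: selection / rendering; the default is identity.  Externally corrected
#: matrices (e.g. from an R integration tool) can be injected here.
BatchCorrector = Callable[[ExpressionMatrix], ExpressionMatrix]


def identity_correction(m: ExpressionMatrix) -> ExpressionMatrix:
    return m


def lognormalize(m: ExpressionMatrix, scale_total: float = 10_000.0) -> ExpressionMatrix:
    """Scale each cell to ``scale_total`` counts, then log1p (natural log)."""
    if m.layer_tag != RAW_COUNTS:
        raise ValidationError("lognormalize expects a raw-counts matrix")
    if scale_total <= 0:
        raise ValidationError("scale_total must be positive")
    totals = m.values.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        ids = [m.cell_ids[i] for i in zero[:10]]
        raise ValidationError(
            f"{zero.size} cell(s) with zero total counts (e.g. {ids}); "
            "filter them before normalization"
        )
    scaled = m.values * (scale_total / totals)[:, None]
    return replace(m, values=np.log1p(scaled), layer_tag=LOGNORM)


def select_hvgs(m: ExpressionMatrix, n_top: int) -> list[str]:
    """Top ``n_top`` highly variable genes by Seurat-flavor dispersion.

    Genes are ranked by the dispersion statistic (variance/mean of the
    de-logged expression) computed on the log-normalized matrix; ties are
    broken by gene name so the panel is deterministic.  The raw dispersion
    is used rather than the mean-bin-normalized variant because the latter
    is only defined relative to a gene's bin neighbours and becomes
    unstable on small or strongly clustered panels.
    """
    import anndata as ad
    import scanpy as sc

    if m.layer_tag != LOGNORM:
        raise ValidationError("select_hvgs expects a log-normalized matrix")
    if not 0 < n_top <= m.n_genes:
        raise ValidationError(f"n_top must be in [1, {m.n_genes}], got {n_top}")
    adata = ad.AnnData(X=m.values.copy())
    adata.var_names = m.gene_names
    sc.pp.highly_variable_genes(adata, flavor="seurat")
    disp = np.nan_to_num(
        adata.var["dispersions"].to_numpy(dtype=np.float64), nan=-np.inf
    )
    order = sorted(range(m.n_genes), key=lambda i: (-disp[i], m.gene_names[i]))
    return [m.gene_names[i] for i in order[:n_top]]


@dataclass(frozen=True)
class CoverageReport:
    n_panel: int
    n_shared: int

    @property
    def coverage_pct(self) -> float:
        return 100.0 * self.n_shared / self.n_panel


def align_to_panel(
    query: ExpressionMatrix, panel: Sequence[str]
) -> tuple[ExpressionMatrix, CoverageReport]:
    """Reorder/reduce the query to the panel's genes; missing genes -> 0.

    Idempotent: aligning an already-aligned matrix is a no-op.  A query
    sharing no genes with the panel almost certainly uses a different gene
    naming scheme and is rejected outright.
    """
    panel = list(panel)
    if len(set(panel)) != len(panel):
        raise ValidationError("panel gene names must be unique")
    pos = {g: j for j, g in enumerate(query.gene_names)}
    shared = [g for g in panel if g in pos]
    report = CoverageReport(n_panel=len(panel), n_shared=len(shared))
    if report.n_shared == 0:
        raise ValidationError(
            "query and panel share no genes; check the gene naming scheme "
            "(e.g. symbols vs Ensembl ids)"
        )
    out = np.zeros((query.n_cells, len(panel)), dtype=np.float64)
    for j, g in enumerate(panel):
        if g in pos:
            out[:, j] = query.values[:, pos[g]]
    aligned = ExpressionMatrix(
        values=out,
        gene_names=panel,
        cell_ids=list(query.cell_ids),
        layer_tag=query.layer_tag,
    )
    return aligned, report
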