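"""Readers and writers for expression matrices and small sidecar files.

Three interchangeable on-disk representations are supported:

* dense CSV/TSV — cells x genes with a header row of gene names and an index
  column of cell ids (or the transpose, with ``genes_as_rows=True``);
* MatrixMarket triplet — ``matrix.mtx`` stored genes x cells (the common
  cell-ranger orientation) with ``features.tsv`` / ``barcodes.tsv`` sidecars;
* AnnData ``.h5ad`` — ``X`` cells x genes with obs/var names.

``read_matrix``/``write_matrix`` dispatch on the path suffix, so every CLI
entry point accepts any of the three.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import ValidationError
from .preprocess import RAW_COUNTS, CoverageReport, ExpressionMatrix


def read_dense(
    path: str | Path, sep: str | None = None, genes_as_rows: bool = False,
    layer_tag: str = RAW_COUNTS,
) -> ExpressionMatrix:
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if genes_as_rows:
        df = df.T
    return ExpressionMatrix(
        values=df.to_numpy(dtype=np.float64),
        gene_names=[str(g) for g in df.columns],
        cell_ids=[str(c) for c in df.index],
        layer_tag=layer_tag,
    )


def write_dense(m: ExpressionMatrix, path: str | Path, sep: str | None = None) -> None:
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.DataFrame(m.values, index=m.cell_ids, columns=m.gene_names)
    df.index.name = "cell_id"
    df.to_csv(path, sep=sep)


def read_mtx(
    mtx_path: str | Path,
    features_path: str | Path | None = None,
    barcodes_path: str | Path | None = None,
    layer_tag: str = RAW_COUNTS,
) -> ExpressionMatrix:
    """Read a genes x cells MatrixMarket triplet with name sidecars."""
    import scipy.io as sio

    mtx_path = Path(mtx_path)
    features_path = Path(features_path) if features_path else mtx_path.with_name("features.tsv")
    barcodes_path = Path(barcodes_path) if barcodes_path else mtx_path.with_name("barcodes.tsv")
    mat = sio.mmread(mtx_path)
    genes = [line.split("\t")[0] for line in _read_lines(features_path)]
    cells = _read_lines(barcodes_path)
    dense = np.asarray(mat.todense() if hasattr(mat, "todense") else mat, dtype=np.float64)
    if dense.shape != (len(genes), len(cells)):
        raise ValidationError(
            f"matrix shape {dense.shape} does not match {len(genes)} features "
            f"x {len(cells)} barcodes"
        )
    return ExpressionMatrix(
        values=dense.T.copy(), gene_names=genes, cell_ids=cells, layer_tag=layer_tag
    )


def write_mtx(m: ExpressionMatrix, mtx_path: str | Path) -> None:
    import scipy.io as sio
    import scipy.sparse as sp

    mtx_path = Path(mtx_path)
    sio.mmwrite(str(mtx_path), sp.coo_matrix(m.values.T))
    mtx_path.with_name("features.tsv").write_text("".join(g + "\n" for g in m.gene_names))
    mtx_path.with_name("barcodes.tsv").write_text("".join(c + "\n" for c in m.cell_ids))


def read_h5ad(path: str | Path, layer_tag: str | None = None) -> ExpressionMatrix:
    import anndata as ad

    return ExpressionMatrix.from_anndata(ad.read_h5ad(path), layer_tag=layer_tag)


def write_h5ad(m: ExpressionMatrix, path: str | Path) -> None:
    m.to_anndata().write_h5ad(path)


def read_matrix(path: str | Path, layer_tag: str = RAW_COUNTS, **kw) -> ExpressionMatrix:
    """Dispatch on suffix: .csv/.tsv/.txt dense, .mtx triplet, .h5ad AnnData."""
    suffix = Path(path).suffix.lower()
    if suffix in {".csv", ".tsv", ".txt"}:
        return read_dense(path, layer_tag=layer_tag, **kw)
    if suffix == ".mtx":
        return read_mtx(path, layer_tag=layer_tag, **kw)
    if suffix == ".h5ad":
        return read_h5ad(path, layer_tag=layer_tag, **kw)
    raise ValidationError(f"unrecognized matrix format: {path}")


def write_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    suffix = Path(path).suffix.lower()
    if suffix in {".csv", ".tsv", ".txt"}:
        write_dense(m, path)
    elif suffix == ".mtx":
        write_mtx(m, path)
    elif suffix == ".h5ad":
        write_h5ad(m, path)
    else:
        raise ValidationError(f"unrecognized matrix format: {path}")


def write_panel(panel: list[str], path: str | Path) -> None:
    Path(path).write_text("".join(g + "\n" for g in panel))


def read_panel(path: str | Path) -> list[str]:
    return _read_lines(path)


def write_coverage_report(report: CoverageReport, path: str | Path) -> None:
    obj = {
        "n_panel_genes": report.n_panel,
        "n_shared_genes": report.n_shared,
        "coverage_pct": round(report.coverage_pct, 4),
    }
    Path(path).write_text(json.dumps(obj, indent=2) + "\n")


def _read_lines(path: str | Path) -> list[str]:
    return [ln.rstrip("\n") for ln in Path(path).read_text().splitlines() if ln.strip()]
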