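"""Gene -> pixel layout and per-cell image rendering.

Each gene is embedded into 2D by a manifold method (t-SNE by default, UMAP
optionally) applied to the gene's expression profile across reference cells,
so co-expressed genes land near each other.  The continuous coordinates are
then snapped to a pixel grid with a linear-sum-assignment step that gives
every gene its own pixel (no collisions).  A cell is rendered by writing its
per-gene min-max-normalized expression at each gene's pixel; unassigned
pixels stay zero.  During training a random subset of gene pixels is zeroed
per image, which teaches the classifier to tolerate genes that query
datasets may lack.

Coordinates are (row, col), 0-based, row-major; this convention is recorded
in the exported map archive.
"""

from __future__ import annotations

import io as _io
import json
import zipfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import ValidationError, sha256_of_text
from .preprocess import ExpressionMatrix

DEFAULT_PERPLEXITY_GRID = (5.0, 15.0, 30.0, 50.0)


@dataclass
class PixelMap:
    """Injective gene->pixel assignment plus rendering statistics."""

    grid_h: int
    grid_w: int
    gene_names: list[str]
    rows: np.ndarray  # (n_genes,) int
    cols: np.ndarray  # (n_genes,) int
    per_gene_min: np.ndarray
    per_gene_max: np.ndarray
    embedding_coords: np.ndarray  # (n_genes, 2) raw manifold coordinates
    projection_seed: int
    projection_method: str
    perplexity: float | None = None

    def __post_init__(self):
        n = len(self.gene_names)
        for name in ("rows", "cols", "per_gene_min", "per_gene_max"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,):
                raise ValidationError(f"PixelMap.{name} must have one entry per gene")
        self.rows = np.asarray(self.rows, dtype=np.int64)
        self.cols = np.asarray(self.cols, dtype=np.int64)
        if self.rows.size:
            if self.rows.min() < 0 or self.rows.max() >= self.grid_h \
                    or self.cols.min() < 0 or self.cols.max() >= self.grid_w:
                raise ValidationError("assigned pixels fall outside the grid")
        flat = self.rows * self.grid_w + self.cols
        if len(np.unique(flat)) != n:
            raise ValidationError("gene->pixel assignment is not injective")
        if np.any(self.per_gene_max < self.per_gene_min):
            raise ValidationError("per-gene max must be >= min")

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    def assignment_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": self.gene_names, "row": self.rows, "col": self.cols}
        )

    def fingerprint(self) -> str:
        return sha256_of_text(
            self.assignment_frame().to_csv(sep="\t", index=False)
            + f"{self.grid_h}x{self.grid_w}"
        )

    # -- persistence: one zip archive of text members -----------------------

    def save(self, path: str | Path) -> None:
        meta = {
            "grid_h": self.grid_h,
            "grid_w": self.grid_w,
            "projection_seed": self.projection_seed,
            "projection_method": self.projection_method,
            "perplexity": self.perplexity,
            "coordinate_convention": "(row, col), 0-based, row-major",
        }
        stats = pd.DataFrame(
            {"gene": self.gene_names, "min": self.per_gene_min, "max": self.per_gene_max,
             "embed_x": self.embedding_coords[:, 0], "embed_y": self.embedding_coords[:, 1]}
        )
        with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
            zf.writestr("assignment.tsv",
                        self.assignment_frame().to_csv(sep="\t", index=False))
            zf.writestr("norm_stats.tsv", stats.to_csv(sep="\t", index=False))
            zf.writestr("metadata.json", json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "PixelMap":
        with zipfile.ZipFile(path) as zf:
            assign = pd.read_csv(_io.BytesIO(zf.read("assignment.tsv")), sep="\t")
            stats = pd.read_csv(_io.BytesIO(zf.read("norm_stats.tsv")), sep="\t")
            meta = json.loads(zf.read("metadata.json"))
        if list(assign["gene"]) != list(stats["gene"]):
            raise ValidationError("corrupt map archive: gene order mismatch")
        return cls(
            grid_h=int(meta["grid_h"]),
            grid_w=int(meta["grid_w"]),
            gene_names=[str(g) for g in assign["gene"]],
            rows=assign["row"].to_numpy(),
            cols=assign["col"].to_numpy(),
            per_gene_min=stats["min"].to_numpy(dtype=np.float64),
            per_gene_max=stats["max"].to_numpy(dtype=np.float64),
            embedding_coords=stats[["embed_x", "embed_y"]].to_numpy(dtype=np.float64),
            projection_seed=int(meta["projection_seed"]),
            projection_method=str(meta["projection_method"]),
            perplexity=meta["perplexity"],
        )


@dataclass
class CellImage:
    """One rendered cell: (grid_h, grid_w, n_channels) intensities in [0,1]."""

    pixels: np.ndarray
    cell_id: str

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3:
            raise ValidationError("CellImage pixels must be H x W x C")


# ---------------------------------------------------------------------------
# gene embedding


def embed_genes(
    reference: ExpressionMatrix,
    method: str = "tsne",
    perplexity_grid: tuple[float, ...] | list[float] | None = None,
    seed: int = 0,
    grid_h: int = 224,
    grid_w: int = 224,
) -> tuple[np.ndarray, float | None]:
    """Embed genes into 2D; returns (coords (n_genes, 2), chosen perplexity).

    For t-SNE with a multi-entry perplexity grid, each candidate layout is
    scored by how many distinct nearest-pixel cells it occupies on the target
    grid (a proxy for spread / few collisions before assignment) and the
    best-scoring perplexity wins, ties going to the smallest value.

    Very small panels (<5 genes) cannot support a t-SNE perplexity at the
    required bound perplexity < (n_genes-1)/3, so they fall back to a
    deterministic PCA layout of the gene profiles (chosen perplexity None).
    """
    n_genes = reference.n_genes
    if n_genes < 2:
        raise ValidationError("need at least 2 genes to embed")
    profiles = reference.values.T  # genes x cells
    bound = (n_genes - 1) / 3.0

    if method == "umap":
        coords = _embed_umap(profiles, seed)
        return coords, None
    if method != "tsne":
        raise ValidationError(f"unknown embedding method {method!r}")

    explicit = perplexity_grid is not None
    grid = tuple(perplexity_grid) if explicit else DEFAULT_PERPLEXITY_GRID
    if explicit:
        bad = [p for p in grid if not p < bound]
        if bad:
            raise ValidationError(
                f"perplexity {bad[0]} too large for {n_genes} genes: "
                f"t-SNE requires perplexity < (n_genes-1)/3 = {bound:.2f}"
            )
    else:
        grid = tuple(p for p in grid if p < bound)
        if not grid:
            return _embed_pca(profiles), None

    if len(grid) == 1:
        return _embed_tsne(profiles, grid[0], seed), grid[0]

    best: tuple[int, float, np.ndarray] | None = None
    for p in sorted(grid):
        coords = _embed_tsne(profiles, p, seed)
        occ = _occupied_cells(coords, grid_h, grid_w)
        if best is None or occ > best[0]:
            best = (occ, p, coords)
    assert best is not None
    return best[2], best[1]


def _embed_tsne(profiles: np.ndarray, perplexity: float, seed: int) -> np.ndarray:
    from sklearn.manifold import TSNE

    n = profiles.shape[0]
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        init="pca" if n > 3 else "random",
        method="exact" if n < 50 else "barnes_hut",
    )
    return np.asarray(tsne.fit_transform(profiles), dtype=np.float64)


def _embed_umap(profiles: np.ndarray, seed: int) -> np.ndarray:
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        from umap import UMAP

        n = profiles.shape[0]
        um = UMAP(
            n_components=2,
            n_neighbors=min(15, max(2, n - 1)),
            random_state=seed,
            n_jobs=1,
        )
        return np.asarray(um.fit_transform(profiles), dtype=np.float64)


def _embed_pca(profiles: np.ndarray) -> np.ndarray:
    from sklearn.decomposition import PCA

    n = profiles.shape[0]
    k = min(2, n, profiles.shape[1])
    coords = np.zeros((n, 2))
    coords[:, :k] = PCA(n_components=k, random_state=0).fit_transform(profiles)[:, :k]
    return coords


def _occupied_cells(coords: np.ndarray, grid_h: int, grid_w: int) -> int:
    scaled = _scale_to_grid(coords, grid_h, grid_w)
    nearest = np.round(scaled).astype(np.int64)
    nearest[:, 0] = np.clip(nearest[:, 0], 0, grid_h - 1)
    nearest[:, 1] = np.clip(nearest[:, 1], 0, grid_w - 1)
    return len(np.unique(nearest[:, 0] * grid_w + nearest[:, 1]))


def _scale_to_grid(coords: np.ndarray, grid_h: int, grid_w: int) -> np.ndarray:
    """Min-max scale raw 2D coordinates onto [0, grid-1] per axis."""
    scaled = np.empty_like(coords, dtype=np.float64)
    for axis, extent in ((0, grid_h), (1, grid_w)):
        lo, hi = coords[:, axis].min(), coords[:, axis].max()
        span = hi - lo
        if span == 0:
            scaled[:, axis] = (extent - 1) / 2.0
        else:
            scaled[:, axis] = (coords[:, axis] - lo) / span * (extent - 1)
    return scaled


# ---------------------------------------------------------------------------
# pixel assignment


def assign_pixels(
    coords: np.ndarray, grid_h: int, grid_w: int
) -> tuple[np.ndarray, np.ndarray]:
    """Optimal injective snap of gene coordinates to grid pixels.

    Coordinates are min-max scaled to the grid extent; the cost of placing a
    gene at a pixel is the squared Euclidean distance between its scaled
    coordinate and the pixel center, and the returned (rows, cols) minimize
    the total cost over all injective placements (rectangular assignment,
    surplus pixels unmatched).
    """
    coords = np.asarray(coords, dtype=np.float64)
    n_genes = coords.shape[0]
    n_pixels = grid_h * grid_w
    if n_genes > n_pixels:
        raise ValidationError(
            f"{n_genes} genes exceed the {grid_h}x{grid_w}={n_pixels} pixel grid"
        )
    scaled = _scale_to_grid(coords, grid_h, grid_w)

    if n_pixels <= 4096 or n_genes * n_pixels <= 2_000_000:
        assignment = _assign_dense(scaled, grid_h, grid_w)
    else:
        assignment = _assign_sparse(scaled, grid_h, grid_w)
    return assignment // grid_w, assignment % grid_w


def _pixel_centers(grid_h: int, grid_w: int) -> np.ndarray:
    rr, cc = np.meshgrid(np.arange(grid_h), np.arange(grid_w), indexing="ij")
    return np.stack([rr.ravel(), cc.ravel()], axis=1).astype(np.float64)


def _assign_dense(scaled: np.ndarray, grid_h: int, grid_w: int) -> np.ndarray:
    from scipy.optimize import linear_sum_assignment

    centers = _pixel_centers(grid_h, grid_w)
    diff = scaled[:, None, :] - centers[None, :, :]
    cost = np.einsum("ijk,ijk->ij", diff, diff)
    rows, cols = linear_sum_assignment(cost)
    out = np.empty(scaled.shape[0], dtype=np.int64)
    out[rows] = cols
    return out

def _assign_sparse(scaled, grid_h, grid_w, k0: int = 128) -> np.ndarray:
    # large grids: restrict each gene to its k nearest pixels and solve the
    # sparse rectangular matching, doubling k until feasible
    import scipy.sparse as sp
    from scipy.sparse.csgraph import min_weight_full_bipartite_matching
    from scipy.spatial import cKDTree

    centers = _pixel_centers(grid_h, grid_w)
    tree = cKDTree(centers)
    n = scaled.shape[0]
    k = min(k0, centers.shape[0])
    while True:
        dist, idx = tree.query(scaled, k=k)
        # +1 offset keeps genuinely-zero costs representable as explicit entries
        data = (dist.ravel() ** 2) + 1.0
        rows = np.repeat(np.arange(n), k)
        cost = sp.csr_matrix((data, (rows, idx.ravel())), shape=(n, centers.shape[0]))
        try:
            r, c = min_weight_full_bipartite_matching(cost)
        except ValueError:
            if k == centers.shape[0]:
                raise
            k = min(k * 2, centers.shape[0])
            continue
        out = np.empty(n, dtype=np.int64)
        out[r] = c
        return out


# ---------------------------------------------------------------------------
# fitting and rendering


def fit_pixel_map(
    reference: ExpressionMatrix,
    grid_h: int = 224,
    grid_w: int = 224,
    method: str = "tsne",
    perplexity_grid=None,
    seed: int = 0,
) -> PixelMap:
    """Embed the reference's genes, snap to pixels, record min/max stats."""
    coords, perplexity = embed_genes(
        reference, method=method, perplexity_grid=perplexity_grid, seed=seed,
        grid_h=grid_h, grid_w=grid_w,
    )
    rows, cols = assign_pixels(coords, grid_h, grid_w)
    return PixelMap(
        grid_h=grid_h,
        grid_w=grid_w,
        gene_names=list(reference.gene_names),
        rows=rows,
        cols=cols,
        per_gene_min=reference.values.min(axis=0),
        per_gene_max=reference.values.max(axis=0),
        embedding_coords=coords,
        projection_seed=seed,
        projection_method=method,
        perplexity=perplexity,
    )


def normalize_vector(vector: np.ndarray, pmap: PixelMap) -> np.ndarray:
    """Per-gene min-max normalization with clipping to [0,1].

    Genes constant in the fitting reference (max == min) map to 0.
    """
    span = pmap.per_gene_max - pmap.per_gene_min
    safe = np.where(span > 0, span, 1.0)
    norm = (vector - pmap.per_gene_min) / safe
    norm = np.where(span > 0, norm, 0.0)
    return np.clip(norm, 0.0, 1.0)


def render(
    vector: np.ndarray, pmap: PixelMap, n_channels: int = 3, cell_id: str = ""
) -> CellImage:
    """Render one panel-aligned expression vector as an image."""
    vector = np.asarray(vector, dtype=np.float64)
    if vector.shape != (pmap.n_genes,):
        raise ValidationError(
            f"expression vector length {vector.shape} does not match the "
            f"{pmap.n_genes}-gene panel"
        )
    norm = normalize_vector(vector, pmap)
    plane = np.zeros((pmap.grid_h, pmap.grid_w), dtype=np.float64)
    plane[pmap.rows, pmap.cols] = norm
    pixels = np.repeat(plane[:, :, None], n_channels, axis=2)
    return CellImage(pixels=pixels, cell_id=cell_id)


def render_batch(
    matrix: ExpressionMatrix, pmap: PixelMap, n_channels: int = 3
) -> np.ndarray:
    """Render all cells; returns (n_cells, n_channels, H, W) for the CNN."""
    if matrix.gene_names != pmap.gene_names:
        raise ValidationError("matrix must be aligned to the pixel map's panel")
    norm = np.clip(
        np.where(
            (pmap.per_gene_max - pmap.per_gene_min) > 0,
            (matrix.values - pmap.per_gene_min)
            / np.where((pmap.per_gene_max - pmap.per_gene_min) > 0,
                       pmap.per_gene_max - pmap.per_gene_min, 1.0),
            0.0,
        ),
        0.0, 1.0,
    )
    imgs = np.zeros((matrix.n_cells, pmap.grid_h, pmap.grid_w), dtype=np.float64)
    imgs[:, pmap.rows, pmap.cols] = norm
    return np.repeat(imgs[:, None, :, :], n_channels, axis=1)


def read_back(img: CellImage, pmap: PixelMap) -> np.ndarray:
    """Invert rendering on assigned pixels: recover the clipped normalized
    vector and undo min-max scaling (constant genes return their min)."""
    plane = img.pixels[:, :, 0]
    norm = plane[pmap.rows, pmap.cols]
    span = pmap.per_gene_max - pmap.per_gene_min
    return norm * span + pmap.per_gene_min


def random_mask(
    img: CellImage, mask_fraction: float, rng: np.random.Generator, pmap: PixelMap
) -> CellImage:
    """Zero a uniformly random subset of assigned gene pixels (all channels).

    Training-time augmentation emulating genes missing from query panels.
    """
    if not 0 <= mask_fraction < 1:
        raise ValidationError("mask_fraction must be in [0, 1)")
    n_mask = int(round(mask_fraction * pmap.n_genes))
    if n_mask == 0:
        return CellImage(pixels=img.pixels.copy(), cell_id=img.cell_id)
    pick = rng.choice(pmap.n_genes, size=n_mask, replace=False)
    out = img.pixels.copy()
    out[pmap.rows[pick], pmap.cols[pick], :] = 0.0
    return CellImage(pixels=out, cell_id=img.cell_id)


def random_mask_batch(
    images: np.ndarray, mask_fraction: float, rng: np.random.Generator, pmap: PixelMap
) -> np.ndarray:
    """Batch variant of :func:`random_mask` on (N, C, H, W) arrays; each image
    receives its own mask."""
    if not 0 <= mask_fraction < 1:
        raise ValidationError("mask_fraction must be in [0, 1)")
    n_mask = int(round(mask_fraction * pmap.n_genes))
    out = images.copy()
    if n_mask == 0:
        return out
    for i in range(images.shape[0]):
        pick = rng.choice(pmap.n_genes, size=n_mask, replace=False)
        out[i, :, pmap.rows[pick], pmap.cols[pick]] = 0.0
    return out
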