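"""Synthetic scRNA-seq generator with a two-level marker structure.

Counts are drawn from a negative binomial around gene-wise baseline means
(overdispersed, as real droplet data is), and class identity is planted as
log-scale mean elevations on disjoint marker blocks: every cell of a
lineage elevates that lineage's shared block, and every cell of a subtype
additionally elevates the subtype's own block — mirroring the
lineage-shared vs subtype-specific signature structure of real immune
populations (e.g. light-chain genes shared across plasma-cell subtypes vs
isotype-specific heavy chains).  Independent Bernoulli dropout then zeroes
entries with a per-gene probability that decays exponentially with the
gene's expected expression — as in droplet data, lowly expressed genes
drop out far more often than highly expressed ones — calibrated so the
overall fraction of zeroed entries equals ``dropout_rate``.  Optional
per-batch additive log-scale shifts emulate the batch effects that
upstream integration would remove.

The generator returns the ground-truth marker map so tests can assert
marker recovery, and is fully deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._utils import ValidationError
from .hierarchy import CellTypeHierarchy, hierarchy_from_dict
from .preprocess import RAW_COUNTS, ExpressionMatrix

#: marker map key: ("base" | "subtype", class name) -> list of gene names
MarkerMap = dict[tuple[str, str], list[str]]


@dataclass
class SyntheticScenario:
    hierarchy: CellTypeHierarchy
    n_cells_per_subtype: int = 120
    n_genes: int = 200
    lineage_marker_block_size: int = 5
    subtype_marker_block_size: int = 5
    lineage_effect: float = 2.0
    subtype_effect: float = 1.5
    dropout_rate: float = 0.3
    nb_dispersion: float = 0.5
    batch_shifts: np.ndarray | None = None  # (n_batches, n_genes) log-scale
    holdout_subtypes: tuple[str, ...] = ()
    seed: int = 7

    def __post_init__(self):
        if self.lineage_effect <= 0 or self.subtype_effect <= 0:
            raise ValidationError("marker effects must be positive")
        if not 0 <= self.dropout_rate < 1:
            raise ValidationError("dropout_rate must be in [0, 1)")
        need = (self.hierarchy.K_base * self.lineage_marker_block_size
                + self.hierarchy.K_sub * self.subtype_marker_block_size)
        if need > self.n_genes:
            raise ValidationError(
                f"marker blocks need {need} genes but n_genes={self.n_genes}"
            )
        for s in self.holdout_subtypes:
            if s not in self.hierarchy.subtype_to_base:
                raise ValidationError(f"holdout subtype {s!r} not in hierarchy")


@dataclass
class SyntheticDataset:
    matrix: ExpressionMatrix              # raw counts
    base_labels: list[str]
    sub_labels: list[str | None]
    marker_map: MarkerMap
    scenario: SyntheticScenario

    def subset(self, keep: np.ndarray) -> "SyntheticDataset":
        keep = np.asarray(keep)
        return SyntheticDataset(
            matrix=ExpressionMatrix(
                values=self.matrix.values[keep],
                gene_names=list(self.matrix.gene_names),
                cell_ids=[self.matrix.cell_ids[i] for i in np.flatnonzero(keep)]
                if keep.dtype == bool else [self.matrix.cell_ids[i] for i in keep],
                layer_tag=self.matrix.layer_tag,
            ),
            base_labels=[b for b, k in zip(self.base_labels, keep) if k]
            if keep.dtype == bool else [self.base_labels[i] for i in keep],
            sub_labels=[s for s, k in zip(self.sub_labels, keep) if k]
            if keep.dtype == bool else [self.sub_labels[i] for i in keep],
            marker_map=self.marker_map,
            scenario=self.scenario,
        )

    def without_subtypes(self, names: tuple[str, ...]) -> "SyntheticDataset":
        """Drop all cells of the given subtypes (holdout-training view)."""
        drop = set(names)
        keep = np.array([s not in drop for s in self.sub_labels])
        return self.subset(keep)

    def only_subtypes(self, names: tuple[str, ...]) -> "SyntheticDataset":
        want = set(names)
        keep = np.array([s in want for s in self.sub_labels])
        return self.subset(keep)


def _dropout_scale(means: np.ndarray, dropout_rate: float) -> float | None:
    """Scale mu0 of the per-gene dropout probability exp(-mu / mu0), chosen
    by bisection so the average zeroing probability equals dropout_rate."""
    if dropout_rate <= 0:
        return None
    lo, hi = 1e-6, 1e8
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if np.exp(-means / mid).mean() > dropout_rate:
            hi = mid
        else:
            lo = mid
    return float(np.sqrt(lo * hi))


def _marker_blocks(scn: SyntheticScenario) -> tuple[MarkerMap, dict, dict]:
    """Lay out disjoint marker blocks at the start of the gene axis."""
    genes = [f"G{i:04d}" for i in range(scn.n_genes)]
    marker_map: MarkerMap = {}
    base_block: dict[str, np.ndarray] = {}
    sub_block: dict[str, np.ndarray] = {}
    cursor = 0
    for b in scn.hierarchy.base_names:
        idx = np.arange(cursor, cursor + scn.lineage_marker_block_size)
        base_block[b] = idx
        marker_map[("base", b)] = [genes[i] for i in idx]
        cursor += scn.lineage_marker_block_size
    for s in scn.hierarchy.subtype_names:
        idx = np.arange(cursor, cursor + scn.subtype_marker_block_size)
        sub_block[s] = idx
        marker_map[("subtype", s)] = [genes[i] for i in idx]
        cursor += scn.subtype_marker_block_size
    return marker_map, base_block, sub_block


def generate(scn: SyntheticScenario) -> SyntheticDataset:
    """Draw the labeled count matrix defined by the scenario."""
    rng = np.random.default_rng(scn.seed)
    hier = scn.hierarchy
    genes = [f"G{i:04d}" for i in range(scn.n_genes)]
    marker_map, base_block, sub_block = _marker_blocks(scn)

    # one group per subtype, plus one per terminal-leaf base
    groups: list[tuple[str, str | None]] = []
    for b in hier.base_names:
        kids = hier.children[b]
        if kids:
            groups.extend((b, s) for s in kids)
        else:
            groups.append((b, None))

    baseline = rng.lognormal(mean=2.0, sigma=0.75, size=scn.n_genes)
    # marker genes share a common baseline so every class has the same
    # expected library size: class identity must come from the marker
    # blocks, not from a depth artifact of per-cell normalization
    marker_idx = np.concatenate(list(base_block.values()) + list(sub_block.values()))
    baseline[marker_idx] = np.exp(2.0)
    n_per = scn.n_cells_per_subtype
    n_cells = n_per * len(groups)
    counts = np.zeros((n_cells, scn.n_genes), dtype=np.float64)
    base_labels: list[str] = []
    sub_labels: list[str | None] = []

    group_means = []
    for b, s in groups:
        mean = baseline.copy()
        mean[base_block[b]] *= np.exp(scn.lineage_effect)
        if s is not None:
            mean[sub_block[s]] *= np.exp(scn.subtype_effect)
        group_means.append(mean)
    mu0 = _dropout_scale(np.array(group_means), scn.dropout_rate)

    n_batches = scn.batch_shifts.shape[0] if scn.batch_shifts is not None else 1
    row = 0
    r = 1.0 / scn.nb_dispersion
    for (b, s), mean in zip(groups, group_means):
        for _ in range(n_per):
            mu = mean
            if scn.batch_shifts is not None:
                mu = mean * np.exp(scn.batch_shifts[row % n_batches])
            counts[row] = rng.negative_binomial(r, r / (r + mu))
            if mu0 is not None:
                drop = rng.random(scn.n_genes) < np.exp(-mu / mu0)
                counts[row, drop] = 0.0
            base_labels.append(b)
            sub_labels.append(s)
            row += 1

    matrix = ExpressionMatrix(
        values=counts,
        gene_names=genes,
        cell_ids=[f"cell{(i):05d}" for i in range(n_cells)],
        layer_tag=RAW_COUNTS,
    )
    return SyntheticDataset(
        matrix=matrix, base_labels=base_labels, sub_labels=sub_labels,
        marker_map=marker_map, scenario=scn,
    )


def standard_hierarchy() -> CellTypeHierarchy:
    """Small default taxonomy: 3 lineages (one terminal), 6 subtypes."""
    return hierarchy_from_dict({
        "T cell": ["CD4 T", "CD8 T", "gdT"],
        "B cell": ["Naive B", "Memory B", "Plasma cell"],
        "NK cell": [],
    })


def standard_scenario(**overrides) -> SyntheticScenario:
    """The canonical desk-scale test fixture.

    3 base types (one terminal) / 6 subtypes, 200 genes, 120 cells per
    group, 5-gene marker blocks with lineage effect 2.0 and subtype effect
    1.5 log-units, 30% dropout, seed 7 — separable enough for a small CNN
    yet small enough for the whole fit/train/annotate/explain chain to run
    in minutes on one CPU.
    """
    params = dict(
        hierarchy=standard_hierarchy(),
        n_cells_per_subtype=120,
        n_genes=200,
        lineage_marker_block_size=5,
        subtype_marker_block_size=5,
        lineage_effect=2.0,
        subtype_effect=1.5,
        dropout_rate=0.3,
        seed=7,
    )
    params.update(overrides)
    return SyntheticScenario(**params)
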