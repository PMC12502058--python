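# Methods

`hicanno` annotates single cells in two stages — lineage (base type) first,
then subtype within that lineage — by rendering each cell's expression
vector as a small image and classifying it with a convolutional network
trained under an adaptive hierarchical focal loss.  This note records the
model, the numerical choices, and what the synthetic benchmark does and
does not demonstrate.

## Tabular-to-image transformation

Each gene receives a fixed pixel on an H×W grid.  Gene coordinates come
from a 2D manifold embedding (t-SNE by default, UMAP optionally) of the
genes' expression profiles across the reference cells, so co-expressed
genes land near each other and convolutions can pool over functionally
related neighbourhoods.  Continuous coordinates are min-max scaled to the
grid and snapped to pixels by solving the rectangular linear sum assignment
problem with squared-Euclidean cost to pixel centers — the optimal
collision-free placement.  Grids small enough for a dense cost matrix use
`scipy.optimize.linear_sum_assignment`; larger grids use a sparse matching
over each gene's k nearest pixels (k doubled until feasible).

Perplexity for t-SNE is chosen from a grid (default 5, 15, 30, 50, filtered
to the admissible bound perplexity < (n_genes−1)/3) by maximizing the number
of distinct nearest-pixel cells the layout occupies before assignment — a
measurable proxy for spread that favours de-collided layouts; ties go to the
smallest perplexity.  Panels with fewer than five genes cannot satisfy the
bound for any grid value and fall back to a deterministic PCA layout; an
explicitly supplied out-of-bound perplexity is an error rather than a
silent fallback.

Pixel intensity is the per-gene min-max normalized log-expression, with the
min/max taken over the *reference* cells so query images are directly
comparable to training images; query values outside the training range clip
to [0, 1].  Genes constant in the reference render as 0.  Normalization is
per-gene, not per-image: per-image scaling would couple every pixel to the
cell's brightest gene.  The default production grid is 224×224 with the
single intensity plane replicated to 3 channels (the standard input shape
of large pretrained backbones); the test and benchmark configuration uses
32×32×1, which is lossless for a 200-gene panel and an order of magnitude
faster.

During training a random subset of gene pixels (default fraction 0.1,
redrawn every epoch) is zeroed — emulating panel genes a query dataset may
lack, whose values are zero-filled at alignment time.  Masking is a
training-time augmentation only.

## Hierarchical classifier

A backbone CNN maps the image to a feature vector; two linear heads produce
base-type logits and one global vector of subtype logits over all lineages.
At inference the base argmax (ties to the lowest index) selects a lineage;
subtype probabilities outside that lineage are zeroed and the survivors
renormalized, so the emitted subtype is a child of the emitted base by
construction.  Renormalization makes the masked vector a proper conditional
distribution over the lineage, which keeps subtype confidences comparable
across lineages with different numbers of children — a property the
rare-population score depends on.  A base type with no subtypes is a
terminal leaf: its masked vector is all zeros and the base call is final.

Two backbones share this interface.  `tiny_cnn` — two 3×3 conv + ReLU + 2×2
max-pool blocks, then a dense feature layer (default 8/16 conv channels,
64 features) — is implemented in numpy with explicit backward passes and an
Adam optimizer, and is the backbone for all desk-scale work; float64
arithmetic makes it bit-reproducible for a given seed on one platform.
`efficientnet_b5` is the atlas-scale option and is constructed lazily from
the optional `torch`/`torchvision` dependency.

## Adaptive hierarchical focal loss

Each level is trained with the focal loss
FL(p) = −(1 − p_true)^γ · log(p_true), mean-reduced over the batch, with
γ = 2.0 (the standard focusing value).  The two levels combine as
L_total = α·FL_base + (1−α)·FL_sub, and after every mini-batch α is updated
by α_{t+1} = β·α_t + (1−β)·FL_base/(FL_base + FL_sub) with momentum β = 0.9,
so training focus drifts toward whichever level is currently harder.  The
backward pass of step t uses α_t; the update produces α_{t+1} for the next
step.  α₀ = 0.5 (equal initial emphasis — also the update's fixed point for
balanced losses); α provably stays in [0, 1] because the update is a convex
combination of α_t and a ratio in [0, 1].  Cells without a subtype label
(terminal leaves, unlabeled) are excluded from FL_sub; a batch with no
labeled cells leaves α unchanged.  If both losses are zero the ratio is
undefined and α is likewise left unchanged.  Mean reduction keeps the
α-ratio independent of batch size.

Training uses Adam (lr 3·10⁻³ for `tiny_cnn`, chosen from its convergence
behaviour on the synthetic benchmark), batch size 32, up to 60 epochs with
early stopping (patience 15) on validation L_total, a subtype-stratified
80/20 split (groups too small to split fall back to base-level strata;
singletons stay in training), and one master seed fanned out to independent
split/mask/init streams.  The α trajectory and both focal losses are logged
per step.

## Rare-population score and ensembles

For each cell the score is max(base_probs) − max(masked subtype probs):
high when the model is confident about the lineage but cannot commit to any
trained subtype — the signature of a population absent from the reference.
Terminal-leaf predictions score 0 (there is no subtype uncertainty to
measure).  A cell is flagged as candidate-novel when base confidence ≥
τ_base (default 0.8) and score ≥ τ_score (default 0.4); both thresholds are
reported alongside the continuous score so users can re-threshold.

A single small network's subtype head extrapolates essentially arbitrarily
on inputs unlike anything seen in training, so its confidence on truly
novel cells is a lottery over initializations.  `hicanno` therefore
estimates the probabilities for rare-population analysis with a small deep
ensemble (default 3 members differing only in master seed; probabilities
averaged before masking) — the standard inexpensive estimator of predictive
uncertainty.  Single-model annotation remains the default for plain
labeling, where the argmax is stable.

## Attribution

Per-gene importance for a class is computed in image space and folded back
through the pixel map (each gene reads its own pixel; unassigned pixels are
ignored), averaging absolute and signed attributions across that class's
cells.  Signed values are kept because depressed genes can be genuinely
discriminative.  Two back-ends share one output schema: `occlusion` — the
attribution of a pixel is score(x) − score(x with that pixel zeroed),
exact by definition and used as the reference — and `expected_gradients`,
a sampled Shapley-style estimate (gradients at random points between the
input and background training images, times input-minus-background,
averaged over 25 samples and a 50-image background by default,
seed-controlled), which scales to large grids where per-pixel occlusion is
too slow.

## Synthetic benchmark

The generator plants a two-level signature structure: disjoint 5-gene
marker blocks per lineage (elevated 2.0 log-units in every cell of the
lineage) and per subtype (additionally elevated 1.5 log-units), mirroring
lineage-shared versus subtype-specific signatures such as light-chain
genes shared across plasma-cell subtypes versus isotype-specific heavy
chains.  Counts are negative binomial (dispersion 0.5) around gene-wise
baseline means drawn log-normally (median scale e² ≈ 7 counts, about 2,000
counts per 200-gene cell — a realistic depth); marker genes share a common
baseline so every class has the same expected library size, preventing the
classifier from reading class identity out of a depth artifact of per-cell
normalization instead of the marker blocks.  Dropout is independent
Bernoulli zeroing with per-gene probability exp(−μ/μ₀) decaying with
expected expression — as observed in droplet data — with μ₀ calibrated by
bisection so the overall zeroing rate equals the configured `dropout_rate`.
Optional per-batch additive log-scale shifts emulate what upstream
integration would remove (off by default; batch correction itself is
delegated to external tools behind an identity hook).

The standard scenario is 3 base types (one terminal), 6 subtypes, 200
genes, 120 cells per group, dropout 0.3, seed 7 — small enough that the
whole fit → train → annotate → explain chain runs in minutes on one CPU.
Under these conditions a nearest-centroid classifier on the noise-free
variant is perfect, the trained CNN reaches ≥95%/≥90% base/subtype accuracy
on fresh draws, a held-out subtype is separated from trained subtypes by
the ensemble rare score at AUROC ≈ 0.85–0.9, and occlusion attribution
recovers the planted markers.

What this does *not* show: the generator has no batch structure by default,
no ambient RNA, doublets, compositional effects, or realistic gene-gene
correlation beyond the planted blocks, and its class structure is far
cleaner than real immune subtypes.  Passing these benchmarks demonstrates
the machinery is correct and the signatures are recoverable when present —
not that real-data accuracy will match the synthetic numbers.

## Numerical conventions and degenerate inputs

p_true is clamped to [10⁻¹², 1] before the log.  Argmax ties break to the
lowest index everywhere.  HVG ranking uses scanpy's raw Seurat-flavor
dispersion (variance/mean of de-logged expression) with ties broken by gene
name; the mean-bin-normalized variant is avoided because its z-scores are
defined only relative to a gene's bin neighbours and invert rankings on
small or strongly clustered panels.  Cells with zero total counts are
rejected at normalization with their identifiers listed.  A query sharing
no genes with the panel is rejected (almost certainly a naming-scheme
mismatch); coverage below 50% warns.  All-zero cells annotate without
error.  Pixel coordinates are (row, col), 0-based, row-major.  Checkpoints
embed fingerprints of the hierarchy and pixel map and refuse to run against
mismatched ones.

## Known limitations

Two taxonomy levels only; deeper trees are rejected.  The numpy backbone is
CPU-bound and meant for panels of hundreds of genes at grids ≤ 64×64;
atlas-scale training (thousands of genes, 224×224, pretrained backbone)
requires the optional torch path.  Batch correction is not reimplemented —
externally corrected matrices plug in ahead of the pipeline.  The rare
score flags candidate populations; it cannot distinguish a truly novel
population from systematic technical shift, and thresholds should be
reviewed per dataset.
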