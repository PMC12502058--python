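# hicanno

Hierarchical image-based cell-type annotation for single-cell RNA-seq.

Annotating immune cells is hierarchical by nature: a cell is first a member
of a major lineage (T cell, B cell, NK cell, ...) and only then a
fine-grained subtype (CD8⁺ T, IgA⁺ plasma, ...), and closely related
subtypes share most of their transcriptome.  Flat classifiers ignore that
structure.  `hicanno` is a toolkit for researchers who want
taxonomy-aware annotation: it renders each cell's expression vector as a
2D image via a manifold layout of genes, classifies it with a two-level
convolutional model, and keeps the two levels consistent by construction.

The core pieces:

- **Gene → pixel maps.** Genes are embedded in 2D (t-SNE/UMAP of their
  expression profiles), then snapped to a pixel grid by linear sum
  assignment so every gene gets its own pixel; pixel intensity is the
  per-gene min-max normalized log-expression.  Random masking of gene
  pixels during training hardens the model against genes missing from
  query panels.
- **Adaptive hierarchical focal loss (AHFL).** Each level is trained with
  the focal loss FL(p) = −(1−p)^γ log p (γ = 2), combined as
  L = α·FL_base + (1−α)·FL_sub with
  α_{t+1} = β·α_t + (1−β)·FL_base/(FL_base+FL_sub), β = 0.9 — training
  focus drifts toward whichever level is currently harder.
- **Probability-masked inference.** Subtype probabilities outside the
  predicted lineage are zeroed and renormalized; lineages without subtypes
  are terminal leaves.
- **Rare-population score.** max(base prob) − max(masked subtype prob):
  high for cells confidently placed in a lineage that match none of its
  trained subtypes — candidate novel populations.  A small deep ensemble
  supplies the calibrated uncertainty this score needs.
- **Per-gene attribution.** Occlusion (exact, definitional) or
  expected-gradients (sampled, fast) attributions per class, folded back
  through the pixel map to ranked gene-importance tables.
- **Synthetic benchmark.** A negative-binomial generator with planted
  lineage-shared and subtype-specific marker blocks, expression-dependent
  dropout, and optional batch shifts makes the whole pipeline testable
  without any external download.

## Worked example

```python
import numpy as np
from hicanno import (standard_scenario, generate, lognormalize, select_hvgs,
                     align_to_panel, fit_pixel_map, render_batch,
                     encode_labels, HierarchicalClassifierConfig,
                     TrainConfig, train_model, evaluate, annotate_cells)

# labeled synthetic reference: 3 lineages (one terminal), 6 subtypes
data = generate(standard_scenario())
hier = data.scenario.hierarchy

ln = lognormalize(data.matrix)                       # 10k counts, log1p
aligned, _ = align_to_panel(ln, select_hvgs(ln, 200))
pmap = fit_pixel_map(aligned, 32, 32, seed=0)        # t-SNE + LSA layout
images = render_batch(aligned, pmap, n_channels=1)
b, s = encode_labels(hier, data.base_labels, data.sub_labels)

cfg = HierarchicalClassifierConfig(image_hw=(32, 32), n_channels=1)
result = train_model(images, b, s, hier, cfg, TrainConfig(seed=0),
                     pixel_map=pmap)

# annotate a fresh draw from the same generator
query = generate(standard_scenario(seed=123))
preds, report = annotate_cells(lognormalize(query.matrix),
                               result.classifier, pmap)
base_acc = np.mean([p.base_label == t
                    for p, t in zip(preds, query.base_labels)])
print(f"coverage {report.coverage_pct:.1f}%  base accuracy {base_acc:.3f}")
print(f"final alpha {result.loss_state.alpha:.3f}")
```

Output:

```
coverage 100.0%  base accuracy 1.000
final alpha 0.410
```

Every query gene was in the model's panel (coverage 100%), all 840 fresh
cells received their generating lineage, and the adaptive weight settled
below 0.5 — late in training the subtype level is the harder one, so it
carries the larger share of the loss.

The same workflow is available from the shell:

```bash
hicanno simulate   --out-dir data
hicanno fit-mapper --reference data/matrix.csv --out map.zip --grid 32 --n-hvg 200
hicanno train      --reference data/matrix.csv --labels data/labels.tsv \
                   --hierarchy data/hierarchy.json --map map.zip --out ckpt.zip
hicanno predict    --query data/matrix.csv --checkpoint ckpt.zip \
                   --map map.zip --out-prefix annotated
hicanno explain    --matrix data/matrix.csv --checkpoint ckpt.zip --map map.zip \
                   --class-name "CD8 T" --method occlusion --out importance.tsv
```

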