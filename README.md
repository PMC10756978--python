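# omics-gsn

Image-based integration of three tumor omics — gene expression, DNA
methylation and copy-number alteration (CNA) — for tumor-grade
classification, built around a from-scratch PaCMAP gene embedding.

## The problem

Bulk multi-omics studies (the motivating case is TCGA prostate
adenocarcinoma graded by Gleason score) measure several molecular layers
for the same samples on incompatible scales. Concatenating the matrices
into one feature vector mixes those scales; `omics-gsn` instead renders
each sample as a small RGB image over a *gene-similarity network* (GSN)
and lets a convolutional network learn from the picture:

1. **Preprocessing** — each omic arrives as a genes × samples TSV
   (cBioPortal-style, first column `Hugo_Symbol`). Expression is filtered
   for variance (`s² ≥ 0.002` by default, computed before normalization),
   all omics are min-max normalized per gene into [0, 1], non-approved
   symbols are dropped, and samples present in all three omics are kept.
   A short list of significant genes (e.g. an external MutSigCV output)
   restricts the dataset; without one, the top-variance genes stand in.
2. **PaCMAP embedding** — each gene, represented by its expression vector
   across samples, is a point `X_i`. Neighbors are picked by the locally
   scaled squared distance `d²_select(i,j) = ‖X_i−X_j‖² / (σ_i σ_j)`,
   where `σ_i` is the mean distance from `i` to its 4th–6th nearest
   neighbors. Three pair classes (neighbor, mid-near, further) drive the
   2-D layout through the losses (with `d̃_ab = ‖y_a−y_b‖² + 1`)

       Loss_NB = d̃/(10+d̃)    Loss_MN = d̃/(10000+d̃)    Loss_FP = 1/(1+d̃)

   combined as `w_NB·ΣLoss_NB + w_MN·ΣLoss_MN + w_FP·ΣLoss_FP` and
   minimized by adaptive-moment gradient descent in three phases (mid-near
   weight annealed 1000 → 3 → 0) from a scaled PCA initialization.
3. **Rendering** — the embedding is frozen into a pixel template; each
   gene gets a disc of fixed radius, filled per sample with
   red = expression, green = methylation, blue = CNA (`round(255·value)`).
4. **Classification** — a compact NumPy CNN (three blocks of 32
   3×3-filters + ReLU, 2×2 max-pool at strides 1/1/2, batch norm, dropout
   0.20/0.20/0.50, dense softmax head) trained with Adam
   (lr 0.05, 80 epochs, 70/30 stratified split).
5. **Evaluation** — recall, precision, accuracy and F1 from one-vs-rest
   confusion counts (micro and macro averaging), plus macro one-vs-rest
   AUC via the rank (Mann–Whitney) statistic.

A seeded synthetic-data generator (`omicsgsn.synthetic_data`) produces
three-omics datasets with planted class-dependent mean shifts, so every
stage is testable end-to-end without any download.

## Worked example

```python
from omicsgsn import SyntheticSpec, generate_multiomics, PipelineConfig
from omicsgsn.pipeline import run_from_matrices

data = generate_multiomics(SyntheticSpec(seed=5))   # 387 samples, 3 classes
cfg = PipelineConfig(image_width=32, image_height=32, radius=3.0, seed=2)
result = run_from_matrices(
    data.expression, data.methylation, data.cna, data.labels,
    data.class_names, cfg, gene_list=data.gene_list,
    approved=set(data.approved_symbols), write_artifacts=False,
)
r = result.report
print(f"test accuracy {r['micro']['accuracy']:.3f}  "
      f"macro OvR AUC {r['auc_macro_ovr']:.4f}  "
      f"(n_train={r['n_train']}, n_test={r['n_test']})")
```

prints

```
test accuracy 1.000  macro OvR AUC 1.0000  (n_train=258, n_test=110)
```

i.e. with the generator's default planted effect (0.2 mean shift between
adjacent classes per signal gene per omic, noise sd 0.08) the held-out
images are perfectly classified — the synthetic classes are strongly
separated across 14 genes × 3 channels. A null dataset
(`SyntheticSpec(effect_size=0.0)`) drops test accuracy to the
majority-class rate (≈ 0.33 for balanced classes), confirming the
pipeline leaks no label information.

The same flow is available from the shell:

```sh
omics-gsn simulate --seed 3 --out data/
omics-gsn run --config config.yaml       # per-stage subcommands also exist
```

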