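# radshape

Statistical shape modelling and automatic classification of distal-radius
fracture morphology from 3-D bone-surface point clouds.

Distal-radius fractures are among the most common fractures seen in
emergency settings, and the major types are defined by geometry: a
Colles-type injury tips the distal fragment dorsally, a Smith-type injury
tips it volarly, and a Barton-type injury displaces the articular block.
`radshape` implements the full morphometric pipeline a shape-analysis lab
would run on segmented CT bone surfaces:

1. **Pose standardization** — voxel-grid downsampling (1 mm), coarse
   principal-axis alignment with optional mirroring (right wrists onto a
   left-sided reference), and point-to-plane ICP (convergence 1e-6, max
   100 iterations, 2.5 mm pair rejection, 0.5 mm RMSE gate).
2. **Correspondence** — each reference point is matched to the nearest
   source point, giving every subject the same point order and count.
3. **Statistical shape model (SSM)** — each corresponded cloud becomes a
   3M-vector; PCA of the 1/(N−1) covariance yields the mean shape T̄,
   eigenvalues λ₁ ≥ λ₂ ≥ … and orthonormal modes φ_k, so any shape is
   T ≈ T̄ + Σ_k b_k φ_k with the plausibility bound |b_k| ≤ 3·√λ_k.
4. **Morphometrics** — six indicators from four expert landmarks
   (A/B: sigmoid-notch volar/dorsal lips, C: styloid vertex, D: Lister's
   tubercle): distances AB, bc, AC, CD and angles ALF, ASR against the
   radius long axis; rule-based typing (dorsal angulation > 20°,
   volar > 20°, articular displacement > 2 mm) and group statistics
   (Shapiro–Wilk, Levene, one-way ANOVA, Tukey HSD).
5. **Classifier** — a three-layer sigmoid network over the first t
   standardized mode coefficients b_k/√λ_k, H = σ(WᵀΦ+B),
   P = σ(VᵀH+C), one independent sigmoid output per class, trained by
   per-sample SGD on cross-entropy; per-class operating thresholds are
   chosen by Youden's J on ROC curves.
6. **Evaluation** — stratified 4-fold cross-validation, one-vs-rest
   pair-counting AUC, confusion matrices and accuracy tables.

Because no public dataset of segmented distal radii exists, the package
ships a first-class synthetic-cohort generator (`radshape.synthetic`): a
stylized bone template with named anatomical features, deformed per group
with known ground truth (applied angulation, displacement, rigid
misalignment and point permutation), at the reference composition of
43 normal / 17 Colles / 12 Barton / 8 Smith subjects with ~2000 points
each.

## Worked example

```python
import radshape as rs

cohort = rs.generate_population(rs.PopulationSpec(seed=1))
config = rs.PipelineConfig(seed=1)   # feature_counts default [5, 10, 15]
result = rs.run_cohort(cohort.clouds, cohort.labels, config)

for f in (5, 10, 15):
    rep = result.reports[f]
    print(f"F={f:<3d} mean 4-fold accuracy: {rep.mean_accuracy:.3f}   "
          f"mean one-vs-rest AUC: {rep.mean_auc:.3f}")
print(result.table2.round(2))
```

prints (80 subjects, a couple of minutes on one CPU):

```
F=5   mean 4-fold accuracy: 0.988   mean one-vs-rest AUC: 1.000
F=10  mean 4-fold accuracy: 0.988   mean one-vs-rest AUC: 1.000
F=15  mean 4-fold accuracy: 0.962   mean one-vs-rest AUC: 1.000
          F=5    F=10    F=15
normal  14.73   27.95   40.71
colles  65.78   82.71   97.22
barton  53.49   92.83  100.00
smith   85.35  100.00  100.00
```

The accuracy is the held-out fraction of the 80 subjects assigned the
correct group label; the AUC is the mean one-vs-rest discrimination on the
training folds. The per-group table shows cumulative variance captured by
the first F modes of each group's own shape model: the 8-subject Smith
group saturates at exactly 100 % by F = 10 and the 12-subject Barton group
by F = 15, because an N-subject PCA model has at most N−1 modes; the large
normal group is dominated by coordinate noise spread over many modes, so
its curve climbs slowly.

The same pipeline is scriptable from the shell:

```sh
radshape simulate --out cohort/ --seed 1
radshape run --manifest cohort/manifest.csv --out report/
```

which writes `cumulative_variance.csv`, `auc.csv`, `thresholds.csv`,
`accuracy.csv` and per-feature-count confusion matrices.

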