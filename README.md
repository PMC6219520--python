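# brainmeth

A three-step DNA-methylation classifier of brain tumors, built as a
reusable, testable pipeline.

Brain metastases — most often from lung cancer (LCBM), breast cancer
(BCBM) or cutaneous melanoma (MBM) — can be hard to tell apart from
primary brain tumors such as glioblastoma, and their tissue of origin or
therapeutic subtype is often uncertain when tissue is scarce or poorly
differentiated.  Genome-wide DNA methylation (the per-CpG beta-value,
methylated signal fraction in [0, 1], from Infinium 450K-style arrays)
carries strong tissue- and subtype-of-origin signal.  `brainmeth`
implements the full derivation and deployment chain of a hierarchical
methylation caller for this problem, for computational biologists working
with beta-value matrices and qMSP panels:

1. **Probe filtering** — sequential exclusion of low-quality,
   sex-chromosome, detection-failed, EPIC-dropped, and
   tumor-vs-normal-uninformative probes, with exact per-stage accounting.
2. **Differential methylation** — per-probe Wilcoxon rank-sum
   (|Δβ| > 0.30, BH q < 0.01), one-way ANOVA
   (F = (SSB/(k−1))/(SSW/(N−k)), Bonferroni-adjusted) and Kruskal–Wallis
   tests; β ≥ 0.9 / ≤ 0.1 dichotomization; variance rankings; marker
   scoring.
3. **Random-forest backward elimination** — repeated 3-fold stratified CV;
   per fold, the top-10,000 probes by class-median range (training samples
   only) are ceil-halved over 15 steps down to a single probe by Gini
   importance (mean decrease in impurity), with a permuted-label null run
   by the same machinery.
4. **Nearest shrunken centroids** — soft-thresholded class centroids
   d′ = sign(d)·max(|d| − δ, 0) for sparse subtype-region selection.
5. **qMSP scoring** — ΔCt = mean Ct_M − mean Ct_U, relative level
   2^(−ΔCt), log-linear standard-curve calibration to percent, composite
   scores (target-type level minus each contrasting type's level), ROC/AUC
   with bootstrap CIs.
6. **The hierarchical caller** — class A (primary CNS vs metastasis, by
   thresholded score), class B (origin, argmax of three scores), class C
   (BCBM subtype, argmax over a six-region panel), with explicit
   abstention on ties.
7. **A synthetic-methylome generator** — Beta-distributed beta-values with
   planted class-specific DMRs, planted filter failures, detection
   p-values and a Ct generative model, plus a ground-truth manifest, so
   every stage is testable without clinical data.

## Worked example

Simulate a three-origin methylome, filter it, and run a reduced
backward-elimination selection:

```python
from brainmeth import (FilterConfig, SelectionConfig,
                       backward_elimination_cv, run_filter_pipeline)
from brainmeth.simulate import SimulationConfig, simulate_methylomes

cfg = SimulationConfig(n_probes=2000,
                       classes=(("BCBM", 15), ("LCBM", 15), ("MBM", 15)),
                       n_dmr_per_class=40, effect_size=0.4, seed=7)
bundle = simulate_methylomes(cfg)
filtered, report = run_filter_pipeline(bundle.matrix, bundle.annotation,
                                       FilterConfig(), normal=bundle.normal)
print(report)

labels = bundle.sample_sheet.labels("origin").loc[filtered.sample_ids]
result = backward_elimination_cv(
    filtered, labels,
    SelectionConfig(n_start=1000, n_steps=10, n_trees=200, n_repeats=3, seed=7))
print(result.summary())
print(result.aggregate_importance(min_features=40).head(5))
```

prints

```
input probes: 2000
  - quality: excluded 40, remaining 1960
  - sex: excluded 40, remaining 1920
  - detection: excluded 4, remaining 1916
  - epic: excluded 20, remaining 1896
  - vs_normal: excluded 10, remaining 1886
retained informative probes: 1886

Backward-elimination cross-validation summary
  classes: ['BCBM', 'LCBM', 'MBM']   repeats: 3   folds: 3   trees: 200
  n_features  median_accuracy
        1000  1.000
         500  1.000
         ...
           2  1.000

cg001908   0.0116
cg001201   0.0115
cg001584   0.0113
cg001770   0.0108
cg001076   0.0108
```

The filter report shows each exclusion stage's count (sequential, so the
counts plus the retained probes sum to the input).  Median held-out
accuracy is 1.0 at every feature-set size on this strongly separable
fixture, and the top Gini-importance regions are all planted DMRs (the
ground-truth manifest `bundle.truth` lets you verify this directly).

A command-line interface mirrors the library
(`brainmeth simulate|validate|filter-probes|dmr|select-features|nsc|qmsp-score|call`);
see `brainmeth --help`.

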