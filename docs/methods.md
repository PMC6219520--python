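# Methods

`brainmeth` implements a three-step DNA-methylation classifier for brain
tumors, together with the statistical machinery needed to derive such a
classifier from Illumina 450K-style beta-value matrices and to validate its
markers by quantitative methylation-specific PCR (qMSP).  This note
documents the models and procedures, their assumptions, the tunable
parameters, and the design choices made where the procedure left them open.

## Data model

A methylome is a probes × samples matrix of beta-values (methylated signal
fraction per CpG probe, in [0, 1]), optionally with a same-shaped matrix of
detection p-values.  Probe annotations carry hg19 point coordinates
(1-based CpG position) and per-probe quality flags; sample sheets carry the
class labels of the three classification tasks (primary vs metastatic
tumor; metastasis origin BCBM/LCBM/MBM; BCBM therapeutic subtype
HR+/HER2−, HER2+, HR−/HER2−).  All analysis runs directly on beta-values;
no M-value transform is applied anywhere.

## Probe filtering

Five sequential exclusion stages produce the informative-probe set:

1. **quality** — SNP overlap, repetitive elements, GC density > 25% of the
   50-bp probe sequence, non-unique mapping, or low mapping quality;
2. **sex** — probes on chrX/chrY or cross-reactive with sex chromosomes
   (for the gender-homogeneous subtype task a switch re-admits X-chromosome
   probes that pass every quality flag);
3. **detection** — detection p > 0.01 in *any* sample, or any missing beta;
4. **EPIC** — probes dropped from the EPIC BeadChip design;
5. **vs-normal** — no significant tumor-vs-normal difference (per-probe
   two-sided Wilcoxon rank-sum, p > 0.05, deliberately uncorrected: the
   stage removes non-tumor signal rather than testing hypotheses).

Accounting is sequential (each stage counts only survivors of earlier
stages), so stage counts plus the retained count always sum to the input
count.  All thresholds are strict inequalities; boundary probes are
retained.  The vs-normal stage pools all metastases against all normals
rather than filtering per origin; per-type pooling would retain slightly
different sets and is not offered.

## Differential methylation

Per-probe tests with pairwise-complete observations and a ≥ 2-per-group
guard:

* **two-group**: Wilcoxon rank-sum with Benjamini–Hochberg FDR; a probe is
  a DMR iff |mean difference| > 0.30 *and* q < 0.01 — the effect-size gate
  is applied after, not instead of, the significance gate;
* **k-group**: one-way ANOVA, F = (SSB/(k−1))/(SSW/(N−k)), with Bonferroni
  (default) or BH adjustment; zero within-group variance with separated
  means is reported as F = +inf, p = 0;
* **rank-based k-group**: Kruskal–Wallis H with tie correction, raw
  p < 10⁻⁴ by default.

Dichotomization calls a beta-value methylated at ≥ 0.9 and unmethylated at
≤ 0.1.  Most-variable-probe ranking supports overall variance and the
range of class medians; ties always break lexicographically by probe id so
rankings are deterministic.  Marker candidates are scored per target class
as (mean in class − mean out of class) − λ·(pooled within-class SD) with
λ = 1 by default; λ is exposed because the "low variance, large
difference" rule is qualitative, and only hypermethylated-in-class probes
qualify.

## Random-forest backward elimination

Per repeat, samples are split into stratified CV folds by seeded
within-class shuffling.  Within each fold, the starting set (default
10,000 probes) is ranked by the range of class medians **using training
samples only**; a forest (default 5,000 trees, sqrt(p) features per split,
unlimited depth) is trained, evaluated on the held-out fold, and the set
is cut to the top half by Gini importance (mean decrease in impurity),
following a ceil-halving schedule of 15 steps that ends at a single probe:
10000, 5000, 2500, 1250, 625, 313, 157, 79, 40, 20, 10, 5, 3, 2, 1.
Importance ties at a cut break by probe id.  "CV performance" is overall
held-out accuracy; one-vs-rest sensitivity and specificity are computed
per model and averaged (with interquartile ranges) across models,
optionally restricted to models with at least a given feature count (40
for the origin task, 10 for the subtype task).  Aggregated importances
average each probe only over the models that contained it.

The permuted-label null runs the identical machinery with labels shuffled
once per repeat; its fold splits are seeded independently of any
real-label run, and the seed makes every result bit-identical across
reruns.  The documented reduced profile for desk-scale runs is 500 trees
and 10 repeats; the full profile (5,000 trees, 100 repeats) changes cost,
not code paths.

## Nearest shrunken centroids

Standard soft-thresholded centroids: per probe i and class k,
d_ik = (x̄_ik − x̄_i)/(m_k(s_i + s₀)) with pooled within-class SD s_i,
stabilizer s₀ = median(s_i), m_k = sqrt(1/n_k − 1/N);
d′_ik = sign(d_ik)·max(|d_ik| − δ, 0) reconstructs shrunken centroids, and
probes with any nonzero d′ are the selected regions (δ = 2.1 by default
for the subtype task).  Prediction minimizes
Σ_i (x_i − x̄′_ik)²/(s_i + s₀)² − 2 ln π_k with priors π_k defaulting to
observed frequencies.  At δ = 0 this is plain nearest-centroid
classification; as δ grows the selected set shrinks monotonically and
prediction collapses to the prior-dominant class.  The historical training
GUI's "minimum correlation" and "number of bins" settings have no
algorithmic counterpart in this formulation; they are carried as inert
provenance fields only.

## qMSP quantification and scores

ΔCt = mean(Ct_M) − mean(Ct_U) over replicates; relative level 2^(−ΔCt).
An undetermined Ct is substituted by a ceiling cycle (default 40, the
common qPCR convention) and flagged.  Percent methylation is calibrated
per region from a five-point two-fold dilution series of a fully
methylated control via least-squares pct = a·ln(rel) + b (natural log,
recorded on the curve object), clamped to [0, 100].

Composite scores subtract each contrasting type's level from the target
type's level, where a "level" is the mean over that type's region(s):
the two-region metastasis-vs-glioblastoma score, the three origin scores
(one region each, two subtracted), and the three subtype scores (two
regions each, the other four subtracted in two pairs).  Scores may be
computed on relative levels or calibrated percent; percent is the default
deployment scale.  ROC AUCs use the Mann–Whitney/trapezoid identity (ties
at 1/2) with a stratified percentile-bootstrap 95% CI (B = 2000) and a
Youden-J operating threshold.  qMSP–array concordance uses tie-adjusted
Spearman correlation with an exact permutation p for tie-free n ≤ 9.

## Hierarchical caller

Step A thresholds the metastasis score (≥ threshold calls metastasis; the
threshold is calibrated from labeled data, never hard-coded).  Step B is
argmax of the three origin scores, step C (BCBM only) argmax of the three
subtype scores; both abstain on an exact tie or when the top-two gap is
below a configurable margin (default 0).  Class B runs only after a
metastasis call and class C only after a BCBM call; a panel missing any
required region raises a structured error and produces no partial call.

## Synthetic data

The generator emulates the data structure the pipeline assumes, not any
particular cohort: per-probe baseline means from Beta(2, 2) clipped to
[0.02, 0.98]; per-sample beta ~ Beta(μν, (1−μ)ν) with concentration
ν = 50 (SD ≈ 0.07 at μ = 0.5, a typical inter-tumor scatter); planted
class-specific DMRs shift the target class mean by the effect size in
whichever direction stays inside (0, 1), redrawing the baseline into the
feasible band when the shift fits nowhere from the drawn value (an error
is raised only when no feasible baseline exists).  Default conditions are
the three-origin setting used by the acceptance analyses: 10,000 probes,
30 samples per class, 150 planted DMRs per class at Δβ = 0.4, 20 normal
samples offset by 0.3 at every informative probe, and small disjoint
planted fractions of probes failing each filter criterion.  Ct values
derive from true methylated fractions m by
Ct = C₀ − log2(template + ε) + N(0, σ) per reaction (C₀ = 28,
ε = 2⁻¹² — placing the no-template Ct at the 40-cycle ceiling — and
σ = 0.2 by default), so the noise-free relative level is
(m + ε)/(1 − m + ε).  A ground-truth manifest (planted ids, true means,
per-criterion failure ids) accompanies every bundle.

What the generator does **not** emulate: probe-type chemistry differences,
batch effects, the genome-wide bimodality of real methylomes (baselines
are unimodal), tumor purity gradients, and correlated neighbouring CpGs.
Passing recovery tests therefore demonstrates correctness of the
algorithms under the stated statistical model, not clinical performance.

## Numerical choices and known limitations

* Deterministic ordering everywhere: ties in rankings, importances and
  NSC selection break by probe id; fixed seeds give bit-identical results.
* The exclusion-count exactness check uses a constructed fixture whose
  uninformative probes interleave tumor and normal values perfectly
  (rank-sum p ≈ 1); with freshly sampled null probes the rank-sum p is
  uniform and ~5% of them would be retained by chance.
* The log-linear standard curve is a global fit to a logit-shaped
  dilution response; at the default background ε its interpolation error
  reaches ~15 percentage points at mid fractions (R² ≈ 0.95 on the
  five-point series).  Calibrated percent is therefore a monotone,
  reproducible scale — adequate for thresholded scores — but not an
  unbiased estimate of the methylated fraction.  Piecewise or logistic
  calibration would remove this bias and is deliberately out of scope.
* Desk-scale problem sizes: the reduced selection profile (500 trees, 10
  repeats) keeps a full three-origin run with its permutation null in the
  minutes range; these sizes are the package's documented test conditions
  and all reported accuracies refer to them.
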