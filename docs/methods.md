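# Methods

`fluidprint` re-creates, as a tested pipeline, a dual-fluid metabolic
fingerprinting workflow for renal tumor diagnosis and prognosis: paired
serum and urine LDI-MS profile spectra are turned into aligned feature
matrices, fused, and fed to a three-step diagnostic cascade, a
biomarker-panel builder with adduct annotation, and a Cox-based risk
model. Because no public cohort accompanies this kind of study, every
stage is validated against a synthetic cohort generator whose ground
truth is recoverable.

## Synthetic cohort model

Each subject contributes one serum and one urine profile spectrum on a
shared m/z grid (default 57,600 points over 100–800 Da, ≈0.0122 Da
spacing). A spectrum is

```
I(m) = Σ_j h_j · N(m; μ_j + ε_j, σ_j)        planted Gaussian peaks
     + A · exp(−(m − 100)/τ)                 chemical baseline
     + η(m),  η ~ N(0, σ_noise), clipped at 0
```

with peak heights

```
h_j = base_j · mult_j(group) · s · u_j,
s   ~ LogNormal(0, σ_sample)   (shared within one spectrum)
u_j ~ LogNormal(0, σ_peak)     (independent per peak)
```

Defaults: σ_peak = 0.15 and σ_sample = 0.10 (per-feature biological +
technical CV ≈ 15% and spot-to-spot CV ≈ 10%, the regime in which
standard-compound CVs stay below ~10% and >90% of within-group
fingerprint pairs score adjusted-cosine similarity above 0.8),
σ_noise = 20, baseline A = 300 with decay τ = 150 Da, m/z jitter
σ = 0.02 Da, peak width σ_j = 0.35 Da. The demo cohort scales a
456-patient renal-tumor composition by 1:10 — 22 ccRCC, 10 pRCC,
10 chRCC, 4 AML plus 20 healthy controls — and plants tumor-level,
malignancy-level and subtype-level intensity multipliers in both fluids.

Disease-free survival for malignant subjects follows exponential
proportional hazards, `hazard_i = h0 · exp(risk_i)`, where the risk is a
planted linear score over peak log-intensity factors; censoring is
independent (probability = censoring rate, censored at a uniform
fraction of the event time), so a censoring rate of 1 yields no events.

The truth record keeps every multiplier, each subject's realized
per-peak log factors, and the survival coefficients. For two groups it
computes the Bayes-optimal AUC of the planted log-normal intensity
model in closed form: log areas are Gaussian with mean shift
Δ_j = log(mult_b/mult_a) and covariance σ_peak²·I plus a rank-one
σ_sample² block per fluid, so the optimal linear discriminant gives
AUC = Φ(√(ΔᵀΣ⁻¹Δ)/√2). Measurement noise and peak-integration error are
not in this bound; including the non-differential "housekeeping" peaks
lets the discriminant cancel the shared spectrum scale, which is why
trained models are benchmarked against the all-planted-features value.

`simulate_fingerprints` emits the planted peak areas directly (no
spectrum rendering) under the same intensity model; Monte-Carlo tests of
the modelling stages use it so their runtime is not dominated by
rendering, while the preprocessing stages are always tested on rendered
spectra.

What the generator does **not** emulate: isotope envelopes, matrix
cluster interferences, mass-calibration drift, heteroscedastic detector
noise, and correlated metabolite panels. Passing recovery tests
therefore demonstrates the pipeline's correctness under the stated
model, not clinical performance on real cohorts.

## Preprocessing

1. **Denoising.** Undecimated (stationary) discrete wavelet transform,
   Daubechies-4, 6 levels; all detail levels soft-thresholded at the
   universal threshold σ̂·√(2 ln n) with σ̂ the MAD of the finest detail
   level. The undecimated transform was chosen over plain decimated
   shrinkage because the latter leaves translation-dependent ringing
   sidelobes (~3–10% of peak height, ~1 Da from tall peaks) that read as
   spurious peaks. The spectrum is padded symmetrically on both sides
   before the transform — the SWT is periodic, and a raw wrap joins the
   two spectrum ends.
2. **Baseline.** A segment-wise low-percentile envelope (3 Da segments,
   10th percentile) first suppresses peaks; a coarse wavelet
   approximation (level 10) of that envelope is then iteratively clipped
   from below the signal and re-smoothed (10 iterations). The output is
   max(signal − baseline, 0). The envelope prefilter exists because the
   approximation of the raw signal undershoots near tall peak clusters,
   and min-clipping then locks in the undershoot.
3. **Peak picking.** Strict local maxima, then four filters: topographic
   prominence ≥ 0.5 × height (flank wiggles of a larger peak have low
   prominence; isolated peaks have prominence ≈ height), SNR ≥ 5 with
   noise = 1.4826·MAD of the signal in a 10 Da window excluding the
   peak's base, height ≥ 50, and shape ratio = trapezoid area /
   (height × base width) ≥ 0.05. A final guard drops candidates dwarfed
   ≥10× by a peak within 1.5 Da (shrinkage shoulders). Peak area is the
   trapezoid integral between flanking minima.
4. **Alignment.** All peaks pooled and sorted by m/z; a gap > 0.3 Da
   starts a new feature (absolute Da, not ppm, since the range is only
   100–800 Da). Feature centroid = area-weighted mean m/z; matrix cell =
   summed area of a sample's peaks in the cluster. Labels render the
   centroid at one decimal, `S<mz>` / `U<mz>`, with `_k` suffixes on
   collisions. No cross-sample intensity standardization is applied.
5. **Log scaling** (`log10(1 + x)`) precedes all model fitting.

The SNR and shape thresholds are operational choices — the upstream
workflow names the filter criteria but not their definitions or values.
Known limitation: peaks ~1 Da apart with a large height ratio (e.g. a
3,000-unit marker beside an 8,000-unit neighbor) merge at this
resolution; their areas fold into the dominant feature.

## Similarity

The adjusted cosine centers each intensity vector by its own mean before
taking the cosine (equivalently, Pearson correlation across features);
constant vectors are rejected as undefined rather than scored 0. The
recommender-style variant (centering each feature by its cohort mean) is
available as `mode="item"`. Scores are computed on aligned fingerprints,
not raw profile traces.

## Diagnosis

Serum and urine matrices are fused along the feature axis (same
subjects, p = p_S + p_U). The train/test split is stratified by class
and resampled (bounded attempts) until age (Welch t-test) and sex
(chi-square) differ between splits with p > 0.05; default ratio 7:3,
with 2:1 used for the smaller subtype models.

Feature selection fits lasso, ridge and elastic net over penalty grids
on standardized features and picks the candidate with the lowest
held-out MSE; features with winner |coefficient| > 0.05 are retained
(top-5 by magnitude as a flagged fallback when none pass). Model search
runs nested cross-validation over a fixed algorithm zoo (LGBM, Extra
Trees, Random Forest, AdaBoost, Gradient Boosting, Decision Tree, KNN,
Logistic Regression, LDA, Naive Bayes, plus a ridge classifier): outer
stratified folds estimate generalization, an inner grid search tunes
each algorithm's small hyperparameter grid by inner-CV ROC AUC, and the
winner is the highest mean outer-fold ROC AUC (ties: fewer grid
combinations, then zoo order), refit on the full training split. Outer
folds are clamped to the smallest class so minority arms stay
cross-validatable. Class imbalance is corrected by random oversampling
to parity, applied inside training folds only; applying it to anything
but training data raises a contract error by construction.

The cascade routes each sample through three fitted stages: healthy
vs tumor, then benign (AML) vs malignant, then one-vs-rest subtype
(ccRCC/pRCC/chRCC) by argmax probability; stages below a routing cut are
not evaluated. Classifiers without probability outputs contribute
sigmoid/softmax-mapped decision scores.

Metrics: ROC AUC by the rank statistic (tested against brute-force
positive–negative pair counting), PR AUC by step integration (average
precision), threshold metrics at 0.5 with the Youden-optimal threshold
reported alongside, Cohen's kappa, and percentile-bootstrap 95% CIs
(default 2,000 resamples over samples). Test rows never enter selection,
tuning, rebalancing or fitting; the suite asserts that poisoning the
test rows leaves every fitted artifact bit-identical.

## Biomarkers

Candidate features must jointly satisfy mean raw intensity > 1000,
model score > 0 (strict), and two-sided p < 0.05 on log intensities
(rank-sum by default, Welch t-test selectable; unadjusted, matching the
stated criterion, with Benjamini–Hochberg values reported alongside).
The model score is the stage model's feature importance for tree
ensembles and the coefficient magnitude for linear models — magnitudes,
not signed values, so down-regulated markers remain selectable; effect
direction is reported separately.

Adduct m/z values use monoisotopic masses from standard atomic masses
plus the cation mass minus one electron (H⁺ 1.00728, Na⁺ 22.98922,
K⁺ 38.96316 Da); a packaged table of ~68 common serum/urine metabolites
(name, formula, stored mass self-checked against the formula to 1e-3 Da
on load) replaces live database queries. Annotation lists all
(compound, adduct) pairs within a mass tolerance (default 0.05 Da),
sorted by absolute error. Panels are scored by a ridge-penalized
logistic model on the panel features only, with orientation-corrected
(≥0.5) univariate AUCs and bootstrap CIs on train and test.

## Prognosis

Features pass a univariate Cox screen (Wald p < 0.1), enter a
multivariate Cox fit (Efron ties, lifelines), and are kept at Wald
p < 0.05; the risk score is the linear predictor Σβ̂_j x_j on log
intensities (features only — whether clinical covariates should enter is
left to the caller, none do by default). Subjects are dichotomized at
the training-median score (configurable); Kaplan–Meier curves, the
two-sample log-rank test, and per-group median disease-free times
(infinite when the curve never crosses 0.5) summarize the separation.
An empty post-filter feature set returns a flagged constant-risk model
instead of failing.

## Numerical and reproducibility choices

* Every stochastic component consumes a `numpy.random.Generator`; a run
  is a pure function of its config, whose single seed is fanned out to
  per-stage substreams. Report JSONs round floats to 8 decimals at write
  time, so identical configs produce byte-identical artifacts.
* Wavelet levels are clamped to what the spectrum length supports;
  degenerate CV folds (single-class) are skipped; an all-zero spectrum
  yields an empty peak list, not an error.
* Problem sizes in the test suite: spectrum-level tests run 20 spectra
  on the full 57,600-point grid (or a 7,200-point grid where peak
  positions, not shapes, are under test); model-level Monte-Carlo checks
  use fingerprint-level cohorts of 200–300 subjects with 20–100
  replicates, sizes at which the recovery targets (elastic-net recall,
  Bayes-AUC band, Cox CI coverage, log-rank power) have comfortable
  margins under the stated generator.

## Known limitations

* The compound table is a curated subset; annotation candidates are not
  identifications (no MS/MS, no retention information).
* The "shape ratio" filter and SNR definition are one reasonable
  operationalization among several; both are fully configurable.
* Cascade probabilities are not calibrated; routing uses 0.5 cuts.
* The exponential survival generator has proportional hazards by
  construction; the Cox stage is not stress-tested against
  non-proportional alternatives.
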