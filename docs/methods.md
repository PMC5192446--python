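# Methods

This note records the models behind `metabosense`, the choices made where
the underlying vendor algorithms are proprietary or underspecified, and what
the synthetic harness can and cannot demonstrate.

## Synthetic cohorts

The generator (`metabosense.synthetic`) emulates a two-group positive-mode
centroid UHPLC-MS acquisition: 9 control and 15 treated samples, retention
time 1–15 min on a 0.005 min scan grid, m/z 100–1000 Da.  Each of 200
metabolites appears in every sample as a Gaussian chromatographic profile
(σ_Rt = 0.025 min, so a peak spans ≳ 40 scans) whose per-scan centroid m/z
is the catalog m/z plus N(0, 0.0015 Da) jitter — about a third of the
narrow 0.005 Da mass tolerance, as for a well-calibrated Q-TOF.

* **Effect structure.**  Ten metabolites discriminate between groups at
  8-fold, five up- and five down-regulated, split symmetrically around a
  geometric-mean base level (treated = base·√r, control = base/√r, so the
  expected treated/control ratio is exactly r).  Balanced directions and
  mid-to-low base abundances (200–2000 counts) keep the treated total ion
  current within biological variation of the control's.  This matters:
  total-intensity normalization divides every feature by the sample total,
  and if a handful of strong unidirectional discriminators inflated the
  treated totals, every background feature would acquire a spurious
  anti-correlation with class (a compositional closure artifact).  In real
  cohorts with thousands of features the discriminators are a negligible
  share of the TIC; with only 200 simulated metabolites, the balanced
  design is what keeps the simulation representative.
* **Diffuse background response.**  Non-discriminating metabolites carry a
  mild heterogeneous response (treated/control ratio lognormal, median 1,
  log-sd 0.1, i.e. mostly 0.8–1.25×), emulating the broad metabolome shift
  of an infected plant.  These produce the borderline variables whose
  selection flips between pipeline variants — the mechanism behind
  method-unique Venn regions.
* **Noise and redundancy.**  Between-sample biological variation is
  mean-preserving lognormal with CV 0.2.  Chemical noise is Poisson per scan
  (0.2 ions/scan), uniform in m/z, uniform 10–250 counts in intensity —
  deliberately straddling the 10/100-count thresholds so the
  intensity-threshold parameter has something to remove.  With probability
  0.3 a metabolite gets a [M+Na]⁺ companion at +21.9819 Da whose per-sample
  intensity tracks the parent exactly (r = 1 before detection noise).
* **Determinism.**  One `numpy` Generator seeded from the design; identical
  designs give bitwise-identical cohorts.

Not emulated: profile-mode spectra, retention-time drift between samples,
instrument drift / QC structure, isotope envelopes, correlated metabolite
blocks (pathways), negative mode, MS/MS.  Passing tests therefore show the
pipeline's behavior under idealized alignment conditions; they say nothing
about Rt-warping robustness, and the "noise level" metric (fraction of
features matching no catalog entry) is a harness surrogate, not the vendor
software's undocumented noise statistic.

## Matrix creation

The vendor peak-picking algorithm is patented and unpublished; this package
fixes a concrete, testable realization of each operation its documentation
names.

* **ROIs.**  Streaming greedy clustering in m/z: an ion joins the ROI whose
  running intensity-weighted center is nearest and within the mass
  tolerance, else seeds a new ROI.  Because centroid jitter is a sizable
  fraction of the tolerance, adjacent ROIs whose centers end within one
  tolerance of each other are merged afterwards — without this, one species
  occasionally splits into duplicate features.
* **Peak detection.**  The EIC (zeros where the ROI has no ion) is smoothed
  by Savitzky–Golay; the same fit supplies first and second derivatives.
  Candidate peaks are maximal runs of negative second derivative; the apex
  is the smoothed maximum inside the run and the run edges are the
  inflection points.  Integration bounds extend outward to the nearest
  local minima (or the grid edge); the baseline is the straight line
  between the bounds; height = apex − baseline, area = trapezoidal
  integral above the baseline.  The width at 5 % of height is measured and
  reported but does not bound the integration: stopping integration at the
  5 % crossing with a chord baseline loses ~11 % of a Gaussian's area,
  whereas the local-minimum rule recovers the closed form h·σ·√(2π) to
  within 2 % on a noiseless peak (a unit test enforces this).
* **Auto settings.**  When the peak width is "auto" it is estimated as the
  median 5 %-height width of the 20 tallest total-ion-chromatogram maxima;
  the SG window is set to about half that width (≈ the FWHM, clipped to
  5–31 odd points).  A window as wide as the full 5 % width over-smooths:
  it halves apex heights and rings at the flanks, producing satellite
  curvature runs.  The baseline-threshold gate compares peak height with a
  noise-equivalent height e^½·s·σ̂ built from the robust scale s of the
  first derivative outside candidate runs and the candidate's inflection
  half-width; auto threshold 3.
* **Alignment.**  Peaks pooled over samples in descending height order; a
  peak joins the nearest existing feature (scaled squared distance) within
  ±0.05 Da and ±0.20 min whose sample slot is free, else seeds a feature;
  consensus Rt/m/z are incremental intensity-weighted means.  Greedy
  descending-height assignment is deterministic and O(n log n); no global
  optimization, no Rt warping.
* **Peak removal.**  A feature is kept iff some sample's height reaches the
  intensity threshold; within a kept feature, values at or above the
  noise-elimination level (default threshold/10 — the vendor never states
  a number) are kept and lower ones become missing.
* **Normalization.**  Each sample's non-missing heights are rescaled to sum
  to 10 000 (the target is arbitrary; downstream scaling removes it).
  Matrix values are peak heights (maximum intensity), not areas.

## Pre-treatment

Transform first, then scale; scaling statistics are computed on the
transformed values.  log10(C₁x + C₂) with C₁ = 1, C₂ = 0 sends non-positive
cells to missing (counted, no pseudo-count) — the missing-aware models
absorb them.  Scaling is column-wise over observed cells with the n−1
standard deviation; zero-variance columns get weight 0 and are excluded
from modeling.  Per-column means and weights are stored, so the pretreated
matrix back-projects exactly and new observations can be scaled with the
training parameters.

## Latent-variable models

* **NIPALS PCA with missing values.**  Score and loading updates are least
  squares over observed cells.  The denominator of each regression is
  floored at 1/3 of its complete-data value — a "correction factor" of 3
  that stops rows or columns observed in under a third of their cells from
  acquiring extrapolated leverage.  (The commercial implementation's
  adjustment is undocumented; this realization is an approximation and can
  be disabled via the `correction` argument.)  Convergence: relative score
  change < 1e-10, at most 500 iterations; sign fixed so the largest
  loading element is positive.  On complete data the result equals the
  truncated SVD to 1e-6 (tested).
* **PCA cross-validation.**  Element-wise deletion: cells are assigned to 7
  groups by (row + col) mod 7; each group is deleted, a one-component model
  fit without it predicts it; Q²_a = 1 − PRESS_a/SS_{a−1}, cumulative
  Q² = 1 − Π PRESS_a/SS_{a−1}.  Components are retained while each adds to
  the cumulative Q² (i.e. Q²_a > 0).
* **OPLS-DA.**  Classes encoded 0/1 (sorted order) and centered.  Repeat:
  w ∝ Xᵀy (unit norm), t = Xw, p = Xᵀt/tᵀt; orthogonal weight
  w_o ∝ p − (wᵀp)w, t_o = Xw_o, p_o = Xᵀt_o/t_oᵀt_o, deflate X by t_o p_oᵀ.
  Orthogonal components are added while observation-wise seven-fold CV Q²
  increases (class-stratified round-robin folds over sorted sample ids,
  deterministic).  Inside each CV fold the column centering is recomputed
  on the training rows only — centering on all samples leaks held-out
  information and inflates Q².  Fold-wise re-estimation of the scaling
  weights is second-order and not performed.  With zero orthogonal
  components the model is exactly one-component PLS (tested against an
  independent implementation).  Prediction removes the orthogonal
  components from the new observation (missing-aware projections), computes
  the predictive score, and assigns the nearer fitted class mean on ŷ.

## Validation battery

* **Hotelling's T²**: T²_i = Σ_a t²_ia/s²_a with limit
  A(N−1)/(N−A)·F_{1−α}(A, N−A); coverage at α = 0.05 verified to
  5 % ± 1 % on 5000 multivariate-normal draws.
* **DModX**: s_i = √(Σ_k e²_ik/(K−A)), s₀ pooled over all cells with
  (N−A−1)(K−A) degrees of freedom, DModX_i = s_i/s₀, D_crit =
  √(F_{1−α}(K−A, (N−A−1)(K−A))).  Mean normalized DModX ≈ 1 under
  homogeneous residuals (verified).
* **CV-ANOVA**: F = ((SS_y − PRESS)/df₁)/(PRESS/df₂) with df₁ = number of
  model components + 1 (predictive + orthogonal + 1) and df₂ = N − df₁.
  The commercial df bookkeeping is proprietary; this allocation is covered
  by the null-rate check (p > 0.05 in ≥ 90 % of permuted-label refits)
  rather than an exact-match claim.
* **Permutation test** (n = 50): labels reshuffled with class sizes
  preserved; each permuted model is refit *at the true model's
  dimensionality* (same number of orthogonal components) rather than
  re-selecting it by CV — a model of equal complexity fit to chance labels
  is the relevant null, and with CV re-selection every permuted model of a
  wide matrix reaches R²Y ≈ 1, which would make the "true model beats all
  permutations" criterion vacuous.  Intercepts come from a least-squares
  line through the permuted (|corr|, R²) and (|corr|, Q²) points plus the
  true model at correlation 1 (alternative excluded by flag).  A model is
  "valid" iff its R²Y and Q² exceed every permuted value.

The permutation and CV-ANOVA calibration checks run on constructed
two-class data (class difference along one direction plus one orthogonal
variance direction plus iid noise) at N = 96 with observation noise sd 1.0.
At the cohort's N = 24 the null Q² distribution intrinsically keeps
15–25 % of its mass above zero — permutations that chance-correlate with a
latent direction are genuinely, if weakly, predictive — so the calibration
claims are tested at a size where the CV estimator can resolve them; the
cohort-scale permutation results are reported, not asserted.

## Feature selection

p₁ is the covariance cov(t, x_k) on the pretreated matrix (the commercial
S-plot axis differs by an internal scaling constant, so the |p₁| ≥ 0.05 cut
applies to the covariance definition and is configurable); p(corr)₁ is the
plain correlation and is checked against a brute-force oracle.  VIP
combines the predictive and orthogonal components with explained-variance
shares as weights (R²Y for the predictive, R²X share per orthogonal
component); Σ VIP² = K holds by construction and is asserted numerically;
a predictive-only variant is available.  The dot-plot confirmation is
reduced to a number: the overlap of the two groups' observed [min, max]
ranges as a fraction of their union range, computed on the normalized
intensities; the default selection requires zero overlap ("a very strong
discriminating variable has no overlap between groups").  Venn/Jaccard
comparisons across pipeline variants use the S-plot + VIP candidate sets
(before the per-variable dot-plot confirmation), matched across variants by
Rt/m/z proximity within the alignment windows, since variants built with
different mass tolerances do not share feature labels.

## Problem sizes and runtime

The shipped experiments use the 24-sample, 200-metabolite cohort
(~10⁴ features at the permissive settings before missing-value filtering,
~250 modeled), 50-permutation validation per grid cell, a 32-sample cohort
for held-out prediction (train 9+15, test 3+5), and 5000 draws for the
Hotelling coverage check.  The full test suite runs in about a minute on
one CPU; the acceptance script in under two.

## Known limitations

* The vendor's modified Savitzky–Golay coefficients, the exact commercial
  peak-tracking model, the commercial missing-value correction and CV-ANOVA
  df bookkeeping are all proprietary; each is replaced by the documented
  realization above and validated against closed forms or null simulations
  instead of against the commercial output.
* No Rt drift, so alignment windows are never stressed; no correlated
  metabolite blocks, so VIP/S-plot behavior under multicollinearity is
  untested; compositional effects of total-intensity normalization are
  only as large as the balanced effect design allows.
* The permutation R² intercept on wide matrices (K ≫ N) is high (~0.9)
  because even chance-label models fit well in-sample; the Q² intercept
  (negative throughout) is the informative diagnostic at this shape, which
  is why model validity leans on Q² and CV-ANOVA.
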