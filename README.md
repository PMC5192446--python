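# metabosense

How much do the knobs of an LC-MS untargeted-metabolomics pipeline change
what you find?  `metabosense` implements the complete desk-side pipeline —
matrix creation from centroid runs, data pre-treatment, chemometric
modeling, model validation and discriminating-variable selection — and a
sensitivity experiment that runs the same data through a grid of
pre-processing parameters (mass tolerance, intensity threshold) and
pre-treatment choices (centering, unit-variance and Pareto scaling, log and
power transforms), then compares what each combination selects.

Because the kind of real two-group plant-infection cohort this workflow is
built for is rarely publicly deposited, the package ships a synthetic
centroid LC-MS generator with planted ground truth (discriminating
metabolites with known fold changes, chemical noise, sodium adducts), so
every stage can be scored against what was actually put in.

It is aimed at metabolomics practitioners and chemometricians who want a
transparent, fully testable reference implementation of this pipeline and a
harness for studying how its stages interact.

## The pipeline

1. **Matrix creation** (`metabosense.peaks`) — centroid ions are grouped
   into m/z regions of interest by mass tolerance; chromatographic peaks are
   detected from the Savitzky–Golay-smoothed EIC via its second derivative
   (apex, inflection points, local-minimum integration bounds, linear
   baseline); peaks are aligned across samples within ±0.05 Da / ±0.20 min;
   a feature is kept if any sample reaches the intensity threshold, with a
   per-sample lowered threshold down to the noise-elimination level; each
   sample is normalized to constant total ion intensity.
2. **Pre-treatment** (`metabosense.pretreat`) — features/samples with > 50 %
   missing values are dropped; optional log10(C₁x + C₂) or (C₁x + C₂)^C₃
   transformation; column-wise centering, UV ((x−m)/s) or Pareto
   ((x−m)/√s) scaling.
3. **Modeling** (`metabosense.models`) — missing-value-aware NIPALS PCA
   (score/loading regressions over observed cells, denominators floored at
   1/3 of their complete-data value) with seven-fold cross-validated
   component retention (keep while Q² increases); two-class OPLS-DA with one
   predictive component and CV-chosen orthogonal components; prediction of
   new observations.
4. **Validation** (`metabosense.validate`) — Hotelling's T² with its
   F-based 95 % limit; DModX against D_crit; CV-ANOVA on the
   cross-validated predictive residuals; a 50-permutation response test with
   R²/Q² intercepts.
5. **Selection** (`metabosense.select`) — S-plot (p₁ = cov(t, x_k),
   p(corr)₁ = corr(t, x_k)) with |p₁| ≥ 0.05 and |p(corr)₁| ≥ 0.5, VIP > 1
   (mean VIP² = 1), and a dot-plot-style confirmation that the two groups'
   intensity ranges do not overlap.
6. **The experiment** (`metabosense.pipeline`) — the 4 processing parameter
   sets × standard pre-treatment, plus 8 pre-treatments on the first matrix;
   Venn/Jaccard comparison of the selected sets and recovery scoring against
   the planted truth.

## Worked example

The numbered scripts under `analysis/` run the whole study; their tables
land in `results/`.

```
$ python analysis/01_simulate_cohort.py 1
cohort: 9 control + 15 treated runs
catalog: 251 ion species (10 discriminating metabolites, 51 Na adducts)
ions per run: 10629 (2801 scans, 0.005 min interval)

$ python analysis/02_build_feature_matrices.py
Method 1: 11855 X-variables, 96.8% noise
Method 2: 317 X-variables, 0.0% noise
Method 3: 11735 X-variables, 97.8% noise
Method 4: 249 X-variables, 0.0% noise
```

Raising the intensity threshold from 10 to 100 counts collapses the matrix
by a factor of ~40 and removes essentially every noise-derived feature, at
both mass tolerances — the feature count and noise level are properties of
the processing settings, not of the sample.

```
$ python analysis/04_pretreatment_grid.py 1
None/None      R2X= 0.967 R2Y=0.935 Q2=0.859 selected=8
Center/None    R2X= 0.185 R2Y=0.978 Q2=0.859 selected=8
UV/None        R2X= 0.144 R2Y=1.000 Q2=0.879 selected=12
Pareto/None    R2X= 0.176 R2Y=0.994 Q2=0.899 selected=11
UV/Log         R2X= 0.146 R2Y=1.000 Q2=0.880 selected=12
Pareto/Log     R2X= 0.280 R2Y=1.000 Q2=0.976 selected=12
UV/Power       R2X= 0.137 R2Y=1.000 Q2=0.867 selected=12
Pareto/Power   R2X= 0.150 R2Y=0.896 Q2=0.756 selected=4
```

One and the same matrix: without scaling the leading PCA component mostly
reproduces overall intensity (R²X 0.967), UV scaling spreads variance over
all variables (R²X 0.144), and the selected discriminating-variable sets
range from 4 to 12 features.  Scored against the planted truth
(`analysis/05_compare_and_score.py`), the 12 grid cells share a common core
of 8 variables, four cells contribute variables no other cell selects, and
sensitivity for the 10 planted discriminators ranges from 0.4
(Pareto/Power) to 1.0 — with zero false selections after the dot-plot
confirmation.

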