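# Methods

## Model and assumptions

The package standardises parametric T1 maps by estimating, per segmented
pixel, the bias its confounding-parameter (CP) environment induces
relative to a reference environment, and subtracting it. The absolute true
T1 of tissue is unobservable (every acquisition scheme has its own
accuracy/precision trade-off), so all estimation is *relative*: each CP is
assigned a reference value assumed bias-free — by default 18 years, male,
the 3.0 T reference scanner category and the MOLLI 5(3)3 b sequence
scheme — and the *target* value per bin is the mean of healthy training
pixels whose selector CPs all equal their references. The regression's
dependent variable is apparent − target, either in ms (`absolute`) or as a
fraction of the apparent value (`relative`); independent variables are the
CP values. Standardised maps become comparable across environments but do
not represent true relaxation times.

Assumptions worth keeping in mind:

* CP effects are stable across subjects and, within a bin, independent of
  the T1 value; binning (≤ 10 bins recommended) relaxes the latter.
* The healthy training pool contains records at the reference environment
  (targets are undefined otherwise; fitting aborts with a configuration
  error rather than imputing).
* Outlying or imprecise acquisitions remain outlying after
  standardisation; imprecision is never repaired.

## Modes and coverage

* **individual** — one regression per CP, trained only on records whose
  *other* CPs equal their reference values ("kept constant" is read as the
  strictest form: equal to the reference, because targets are only defined
  there). Best isolation, smallest usable subsets; CP values without a
  usable subset are recorded as *uncovered* and contribute zero bias at
  application, with a log note.
* **cascaded** — the first CP is fitted like the individual mode; the
  whole training set is then standardised for that CP before the next fit,
  so CP *k* only requires CPs *after* it in `cp_order` to sit at
  reference. Order-dependent; the order is stored in the model. Default
  order: age, sex, scanner, sequence.
* **ensemble** — one regression per bin on the full CP vector; categorical
  CPs are integer-coded by lexicographic label order (frozen in the
  codebook). Catches cross-dependencies best but raises an application
  error for categories absent from training.

Categorical submodels in individual/cascaded mode are "intercept-only"
fits of the configured regressor on a constant zero feature: for linear
and tree regressors the prediction equals the per-category mean bias, for
the linear SVR its epsilon-insensitive intercept. One global per-bin
target table (all CPs at reference) serves every mode: in the
individual-mode subsets the concerned-CP-at-reference records coincide
with the all-reference records, and in cascades the all-reference records
are invariant under earlier standardisation steps up to estimation noise.

## Relative y-type

The relative bias is defined as b = (apparent − target) / apparent and
converted back to ms at application as b × current value; in cascades,
component *k* uses the value already corrected by components 1..k−1, and
the bin is re-assigned from the corrected value at each step (mirroring
training, where later fits see standardised pixels). This keeps the
inverse map single-pass and bounded for b < 1. The denominator choice
(apparent rather than target) is a package decision; only the general
absolute/relative distinction is standard.

## Binning

Pooled segmented training values are partitioned by one of eight
algorithms: equal-distant (equal width over [min, max]), equal-size
(occupancy differs by ≤ 1), four agglomerative linkages, k-means and
Gaussian mixture (scikit-learn, seeded). Every clustering is reduced to
ordered half-open intervals via midpoints between adjacent clusters'
extreme members, extended to ±∞ — unseen values at application time land
deterministically in an edge bin, and assignment is monotone. Boundary
ties go to the upper bin. Degenerate inputs (all values equal, more bins
than values, clusters not separable into ordered intervals) raise
configuration errors. Because sklearn's agglomerative clustering is
O(n²), clustering-based partitions subsample deterministically to at most
5000 values; the equal-* rules always use all values. More than ten bins
warns but proceeds.

## Pipeline selection

COV = σ/μ uses the sample (n−1) standard deviation — the test-set COV is
an inter-subject dispersion estimate. It is computed across test *maps* by
default; a `per_subject` switch averages per subject first. Stage-1 ties
are broken by enumeration order (regression type, then y type, then mode)
for reproducibility; failed settings (e.g. ensemble meeting an unseen
category, or a clustering that cannot produce the requested bins) are
excluded from the top-3 rather than imputed, and settings whose COV
exceeds the unstandardised baseline are flagged as worsening.

## Statistics

Cohort comparison routes on Shapiro-Wilk normality of *every* group at
α = 0.05: t-test + one-way ANOVA if all pass, otherwise Mann-Whitney-U +
Kruskal-Wallis; a pair is significant only if both its pairwise p and the
omnibus p are ≤ α. No multiple-testing correction is applied beyond this
dual-test rule. Constant groups force the nonparametric route with a
warning. Confidence intervals are two-sided 95 % t-intervals of the mean
(the interval method is a package choice). ROC analysis classifies
positive at value ≥ threshold (disease raises native T1), enumerates
candidate thresholds at midpoints between consecutive pooled unique
values plus ±∞, picks the Youden-J maximiser (ties → lowest threshold),
and computes AUC by the rank formulation with ties counted ½. Evidence of
discrimination requires sensitivity + specificity ≥ 150 %.

## Synthetic cohorts

The generator emulates pooled multi-study healthy (and diseased) data:
per subject a base T1 ~ N(1150, 40²) ms, integer ages 18–80, categorical
scanner/sequence/sex draws; per map an age slope (0.8 ms/year), category
effects (multiplicative before additive; defaults: 1.5 T scanner
−150 ms, female +20 ms, MOLLI 3(3)5 −30 ms), a disease offset (HCM
+50 ms, AMY +200 ms — magnitudes chosen so standardised cohort
separations sit in the range reported for these diseases), then Gaussian
pixel noise (30 ms) inside a rendered annulus mask. The default healthy
design is *anchored*: ~20 % reference-environment subjects, ~50 % in
blocks that vary exactly one CP (others at reference; emulating the
controlled sub-studies real pooled collections contain, and making the
individual/cascaded modes trainable), the rest fully mixed. The
ground-truth table records every injected component exactly, providing
the oracle for recovery tests.

What the generator does **not** emulate: MR sequence physics (MOLLI/SASHA
inversion-recovery behaviour, heart-rate dependence), spatially
structured tissue heterogeneity or segmentation error, scanner drift, and
correlations between CPs and disease. Passing tests therefore demonstrate
that the estimation machinery is correct and self-consistent under known
injected biases — not that real clinical cohorts harmonise to any
particular COV.

## Numerical and design choices

* Training samples are individual segmented pixels (required for
  multi-bin partitions to be meaningful), but a map's CP vector is
  constant, so application needs one regressor call per occupied bin.
* Tree ensembles use 1000 trees, seeded from the setting; all other
  regressor hyperparameters stay at library defaults.
* All pixel math is float64; identical inputs and seed give bit-identical
  results (tested, including forests).
* Archives store a JSON manifest (setting, CP definitions, partition,
  targets, codebooks, optional training fingerprint, linear coefficients
  inlined portably) plus pickled estimators with the scikit-learn version
  recorded; loading checks the format version.
* Numerical reference matching is exact equality; ages are integer years
  (DICOM "nnnY"), and the anchored design pins reference subjects at the
  reference age.

## Problem sizes

Tests and the acceptance script run on desk-scale phantoms (16–32 px
images, ~50–200 myocardial pixels per map, 6–60 subjects), chosen so the
full 240-setting sweep — including the 1000-tree forests — completes in
minutes while every statistical property under test (offset recovery to
±10 ms at 30 ms noise, COV reduction, ROC evidence) is already decisive
at these sizes. The acceptance grid search uses a two-CP (scanner,
sequence) universe; the four-CP universe is exercised by the recovery and
diagnostic computations.

## Known limitations

* Only one numerical CP (age) is supported by the synthetic generator;
  the estimation machinery itself is agnostic.
* Individual mode is data-hungry by construction and will leave CP values
  uncovered in unbalanced collections — mirroring its known behaviour —
  and uncovered values pass through unstandardised.
* The relative cascade's composition order and denominator are package
  conventions; alternative conventions would give slightly different
  (equally defensible) results.
* Multi-frame/enhanced DICOM, DICOM-SEG masks and image registration are
  out of scope; masks must share the pixel grid exactly.
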