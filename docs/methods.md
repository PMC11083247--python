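# Methods

## Fingerprint model

A GC/MS acquisition is a scan-by-channel intensity map. The total ion
spectrum (TIS) collapses it along retention time: the value at integer
channel k is the sum of intensities recorded at nominal mass k over all
scans. Profile-mode masses are binned by rounding to the nearest integer
(ties to even). The fingerprint window is m/z 50–550 inclusive — 501
channels — even where acquisition scans wider; both bounds are exposed as
options. Each spectrum is then base-peak normalized (divided by its own
maximum), always per sample and never globally, so fingerprints encode
relative abundances and the largest channel is exactly 1.

All downstream statistics operate on normalized fingerprints. The
headspace-optimization response is the Euclidean distance between the
fingerprints of a *Slight* (25 % non-hydrogenated) and a *Very Strong*
(100 %) wax: larger distance = better grade separation. The distance is
deliberately defined only on normalized spectra; unnormalized input is an
error rather than a silent rescale.

## Response-surface stack

The three headspace factors are coded affinely onto [−1, 1]
(low ↔ −1, mid ↔ 0, high ↔ +1): temperature 100/120/140 °C, agitation
250/500/750 rpm, sample quantity 0.2/0.4/0.6 g. The design is the
three-factor Box–Behnken: all twelve edge midpoints (each factor pair at
(±1, ±1), third factor at 0) plus n_center = 6 center replicates. Run-order
randomization is seed-controlled and affects an order column only.

The model is the full 10-term quadratic fitted by OLS in coded units.
Inference follows the replicated-center-point convention of classical RSM
software:

* **Pure error** is the sample variance of the center replicates
  (df = n_center − 1 = 5); it is the denominator of every term F-test and
  of the lack-of-fit F. Residual-MS denominators give materially different
  p-values and do not reproduce the bundled study's printed table.
* **Term sums of squares** are partial (Type III),
  SS_j = b_j² / (XᵀX)⁻¹_jj, which reduces to 8 b_j² for the orthogonal
  linear columns and 4 b_j² for interactions. Because the quadratic
  columns are not mutually orthogonal, the partial SS do not sum exactly
  to the model SS; the identities that hold exactly (and are tested) are
  SS_model + SS_resid = SS_total and SS_lof + SS_pure = SS_resid.
* **Standardized effects** are t = b_j / se(b_j) with pure-error-based
  standard errors, so t² equals the ANOVA F for single-df terms; the
  Pareto significance line is the two-sided t critical value at α = 0.05
  with 5 df.
* **Optimization** maximizes the fitted polynomial over the closed coded
  cube by multi-start L-BFGS-B (corners + center + seeded random starts),
  cross-checked by a coarse-to-fine grid scan at 0.001 resolution. On the
  bundled study the maximizer is the corner (+1, −1, +1); the reduced
  significant-terms equation is reported alongside but all inference uses
  the full model. Coded coordinates convert to natural units by the same
  affine map used for coding (so +0.9708 on the sample-quantity axis maps
  to 0.594 g).

The kinetic study (incubation time 5–25 min) is a classical one-way ANOVA
on replicate distances per time, with the decision at 95 % confidence;
a non-significant result supports fixing the shortest time. Precision is
the coefficient of variation of replicate distances (sample s.d. over
mean, ×100) checked against a 10 % acceptance limit (a CV of exactly 10 %
passes).

## Chemometrics

**HCA** treats samples as points in the 501-dimensional fingerprint space
with the Euclidean metric. The linkage method is selected by the
agglomerative coefficient, AC = mean over samples of
(1 − h_first / h_final), where h_first is the height at which a sample
first merges; Ward linkage is implemented in the squared-distance
(Ward.D2) sense via SciPy's Lance–Williams recurrence — stated explicitly
because "Ward" differs across ecosystems. Dendrograms export as Newick
plus a merges CSV so any plotting layer can render them.

**PCA** is mean-centered without unit-variance scaling: channels already
share the base-peak-normalized scale, and scaling would inflate noise-only
channels (a `scale` flag exposes the alternative). Components are computed
by SVD; each component's sign is fixed so its largest-|loading| channel is
positive, making output deterministic.

**Supervised protocol.** Samples are split 70/30 stratified by grade
(per class, round-half-up of 0.7 · n goes to training, so 75 samples split
55/20); stratification guarantees all five grades on both sides, matching
the partition the protocol presumes. Hyperparameter search and training
use stratified, seed-fixed 5-fold CV (a continuous response falls back to
plain shuffled folds).

* *Gaussian SVM/SVR*: kernel k(x,x′) = exp(−σ‖x−x′‖²), so σ maps directly
  onto scikit-learn's `gamma` (and onto the γ some reports print). The
  grid is exhaustive: log₂C and log₂σ from −10 to 10 in 0.5 steps, 41 × 41
  = 1681 combinations; classification selects maximum CV accuracy,
  regression minimum CV RMSE, ties broken by smallest C then smallest σ.
  SVR keeps ε = 0.1.
* *Random forest*: bagged decision trees with per-split feature
  subsampling, built on scikit-learn's Bagging ensembles because they
  expose per-tree bootstrap samples, which the importance computation
  needs. mtry defaults to ⌊√p⌋ (classification; √501 = 22.38 → 22) and
  ⌊p/3⌋ = 167 (regression); the ntree stability sweep covers 2–100 in
  steps of 2 with the final forest at 100 trees. OOB error aggregates
  out-of-bag votes (or means) per sample. Importances are per-tree
  out-of-bag permutation importances in the mean-decrease-accuracy
  convention: for each tree, the error increase on its OOB samples when
  one channel is permuted (averaged over 5 permutation draws to stabilize
  small OOB sets), averaged over trees and divided by the standard error,
  then min-max scaled to 0–100. The per-tree formulation matters: whole-
  forest permutation importance collapses on redundant marker channels,
  while per-tree importance credits every channel the trees actually use.
* *Channel reduction*: channels with relative importance above 70 are
  kept and the forest refit on them alone (falling back, with a warning,
  to the top-k if the threshold selects nothing); a per-channel one-way
  ANOVA across grades documents the selection. For a reduced set of 8
  channels the refit uses mtry = ⌊√8⌋ = 2.
* *PLSR*: component count minimizes 5-fold CV RMSE; variance explained in
  predictors and response is reported. Importances are variance-weighted
  sums of absolute component weights (each component's |weights| scaled by
  the response variance it explains), min-max scaled to 0–100.
* *Metrics*: accuracy and unweighted Cohen's kappa for classification.
  For regression, RMSE and R²; R² is reported as the squared Pearson
  correlation between predicted and observed (the convention of the
  tuning framework this protocol mirrors — insensitive to calibration
  bias), with the 1 − SS_res/SS_tot form available as
  `r_squared_classic`. The DOE R² uses 1 − SS_res/SS_tot.

**Spectralprints** are per-grade means of the normalized intensities at
the reduced channels, renormalized to each grade's maximum for display.

## Synthetic study generator

The generator emulates the 75-run design: 5 lots (A–E) × 5 blend levels
(0/25/50/75/100 % non-hydrogenated wax ↔ grades None…Very Strong) × 3
replicates, labelled `25%_A_R1`-style. Each run's expected fingerprint is
a marker table (9 grade-dependent ions: m/z 79, 91, 92, 95, 97, 118, 157,
188, 221) plus a grade-independent hydrocarbon background (8 ions, all
below the marker base peaks). The default marker means are chosen to
satisfy the qualitative grade fingerprint: base peak at m/z 97 for
None/Slight and m/z 92 for Moderate/Strong/Very Strong; m/z 92/118/157 at
≥ 0.75 for Slight but < 0.5 for None; the seven non-dominant markers
non-increasing from Moderate to Very Strong; and m/z 91 (the
alkylbenzene/tropylium fragment) rising monotonically with grade, which
makes it the dominant PCA loading and regression predictor. Exact bar
heights within those constraints are the package's own choice and ship as
an editable table; the constructor validates any replacement against the
same rules.

Stochastic structure, applied on the normalized-intensity scale:

* **Lot effect** — multiplicative log-normal factor per (lot, ion),
  σ = 0.05 by default, derived from the generator seed and the lot label
  so replicates of a lot share it. This creates the within-grade
  sub-structure hierarchical clustering sees.
* **Instrument noise** — additive Gaussian per channel, σ = 0.02 by
  default (≈ 2 % of the base peak, a realistic relative noise floor for
  summed single-quad intensities), clipped at zero for physical
  non-negativity.
* **Chromatography** — each signal ion is laid out in time as a single
  Gaussian peak (s.d. 3 scans, deterministic per-ion retention position);
  residual channels get a flat profile. Peak shape is cosmetic: the
  fingerprint integrates over time, and time integration recovers the
  channel totals exactly, which the conservation tests exploit.

With noise and lot effects off, the normalized fingerprint equals the
marker table exactly. Everything is reproducible: the generator seed
drives lot effects, a per-run seed drives noise, and identical arguments
give bit-identical runs.

What the generator does *not* emulate: headspace physics (temperature/
agitation kinetics — the DOE test surrogate is a known polynomial, not a
mechanistic model), co-eluting real compounds, detector saturation,
retention drift, or correlated noise. Passing the planted-recovery tests
therefore shows the statistical machinery is correct under the assumed
structure, not that real wax data will separate this cleanly.

A `SurrogateSurface` (known 10-coefficient quadratic + Gaussian noise,
defaulting to the bundled study's fitted coefficients) provides the DOE
oracle: fitting noiseless surrogate responses recovers the planted
coefficients to 1e-10, which pins the whole least-squares path.

## Problem sizes and numerical choices

The test suite runs the full protocol at the study's own scale (75
samples, 501 channels, 1681-point SVM grids, 100-tree forests); the
stochastic acceptance checks average 5 study seeds for the classifier and
regressor and 3 seeds for marker recovery, and calibrate the kinetic ANOVA
on 1000 null simulations — about three minutes of CPU in total. The
surface optimizer's grid cross-check uses a 0.02 coarse pass refined to
0.001 locally, equivalent to the full fine grid for a quadratic. Degenerate
inputs fail loudly: all-zero spectra, single-class training data,
zero-variance responses, missing center replicates and rank-deficient
designs all raise with the offending sample or stage named.

## Known limitations

* The bundled study is the only real dataset; every other number in the
  test suite is synthetic by construction.
* Reported test metrics on any real 75-sample dataset depend on the exact
  random split of the original software environment and are not
  reproducible bit-for-bit; the package therefore validates against
  planted structure rather than against printed hold-out metrics.
* mzML support targets the subset this package writes (centroided MS1,
  64-bit float arrays, optional zlib); it is not a general-purpose reader.
* Only the three-factor Box–Behnken design is implemented; no
  central-composite or D-optimal designs, no multi-response desirability.
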