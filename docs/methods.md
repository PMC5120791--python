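# Methods

`cbfsurrogate` asks a clinical-statistics question on simulated data: can
cerebral blood flow (CBF), as measured by pCASL perfusion MRI in a
middle-cerebral-artery (MCA) territory, be predicted from transcranial
Doppler (TCD) blood-flow velocity plus ten easily available clinical
covariates?  The pipeline has five parts — cohort simulation, regression
forests, iterative imputation, a Poiseuille flow estimator, and grouped
leave-out cross-validation — documented here with their assumptions,
defaults and limitations.

## Synthetic cohort

Real patient-level data of this kind is not publicly available, so every
downstream stage is exercised on simulated cohorts whose *marginal*
structure matches the published summary statistics of an 88-patient,
261-measurement elderly cohort:

* one row per (patient, side, visit); a patient with k measurements
  attends ceil(k/2) visits, each contributing a left and right MCA row
  (single left row on the last visit when k is odd);
* measurements-per-patient distribution {1:1, 2:49, 3:1, 4:32, 5:1, 6:3,
  8:1} (261 rows over 88 patients);
* disease groups healthy / hypertensive / diabetic / both at
  28 : 41 : 2 : 17, assigned by largest remainder; the three diseased
  subgroups share the pooled "diseased" covariate moments because only
  healthy-vs-diseased moments are published;
* side-independent covariates (hematocrit %, intracranial volume ml,
  height m, BMI kg/m², age y, head length dm) drawn once per patient from
  zero-truncated normals with group-specific (mean, sd); side-dependent
  variables (TCD velocity cm/s, MCA diameter mm, CBF ml/min/100g) have
  (group, side)-specific moments.

Side-dependent variables decompose into a per-(patient, side) latent
carrying 70% of the variance and visit-level noise carrying the remaining
30% (`visit_variance_fraction = 0.3`), so repeat visits resemble each
other — the structure the same-time exclusion design needs.  Negative
draws of the composite are rejected by re-drawing the visit-level noise,
preserving the latent structure while keeping all physical quantities
positive.

**Response model.**  Two regimes:

* `mode="null"`: standardised CBF = √ρ·z_patient + √((1−ρ)(1−f))·z_side +
  √((1−ρ)f)·ε, independent of every predictor given group and side; ρ is
  `lr_cbf_correlation` (default 0.7 — the source data show left and right
  CBF to be clearly correlated within a patient but report no
  coefficient) and f the visit fraction.
* `mode="planted"` (default): standardised CBF = Σ_j c_j·z_j +
  patient offset + noise, rescaled to the configured (group, side) CBF
  moments.  The default plants weak covariate coefficients
  (bfv 0.20, hct 0.20, age −0.15, icv 0.10, bmi −0.10; Σc² ≈ 0.12 of a
  total variance ≈ 1.05) under a strong patient offset (sd 0.85) and
  residual noise (sd 0.45).  This is the package's model of the study
  regime: most of the predictable variance is *patient identity*, not
  covariate signal, which is what produces high leave-one-measurement-out
  correlations next to a weak leave-one-patient-out correlation.

**Missingness.**  Cells go missing independently (MCAR) with per-variable
probability; the default puts equal probability q ≈ 0.0908 on the seven
measured numeric predictors, calibrated so the expected number of
complete rows is 261·(1−q)⁷ = 134.  The per-column observed counts of
the source tables are *not* reproduced: they are jointly inconsistent
with 134 complete rows under independent missingness (the real mechanism
was evidently block-structured), and the calibrated-complete-rows
property is the one the pipeline depends on.  A user-supplied mask hook
supports arbitrary mechanisms.  Mass and insonation angle are generated
for 98 randomly chosen rows by default (mass 230±30 g, angle uniform on
[0°, 40°]) and missing elsewhere.

What passing tests on these cohorts show: the machinery is calibrated,
leak-free and able to recover planted structure.  What they cannot show:
anything about the true predictor→CBF relationship in patients —
physiological dynamics, acquisition artefacts and non-MCAR missingness
are all outside the generative model.

## Regression forest

CART-style recursive partitioning, written from scratch (the compiled
kernels in `_kernels.py` are the implementation, not a wrapper):

* split criterion: maximal reduction in within-node sum of squared
  errors of a constant fit — equivalently maximal between-child variance;
* numeric thresholds at midpoints between consecutive distinct sorted
  values; categorical splits on level subsets, with the optimal subset
  found exactly by ordering levels by mean response (valid for
  squared-error regression; all factors in this schema are binary anyway);
* stopping: a node splits only if it holds ≥ `n_min` rows *and* the best
  split strictly reduces the error (a relative floor of 1e-12 rejects
  numerically-zero gains on constant responses); leaves predict their
  training-mean response, so predictions can never leave the training
  response hull;
* ensemble: `T` trees, each on an independent bootstrap resample of size
  N, with `m` candidate predictors drawn uniformly without replacement
  *per node*; prediction is the unweighted tree average.  Defaults
  T = 500, m = 3, n_min = 5 for the 11-predictor table.

Determinism: a master `SeedSequence` spawns one stream per tree; each
node's candidate draw is keyed to its depth-first node id via a
pre-generated key matrix, so fits are reproducible and (without
bootstrap) invariant to training-row permutations.  Ties between equally
good splits go to the earlier schema column, then the smaller threshold.
On small all-numeric tables the deterministic tree (m = p, no bootstrap)
is tested to reproduce a brute-force exhaustive CART's leaf partition
and leaf means; split-variable identity is additionally checked on a
fixed table (on random tables, exactly tied gains — two variables
inducing the same row partition — make variable identity float-order
dependent, while the partition is invariant).

## Iterative imputation

The missForest-style scheme: mean/mode initialisation, then per column
(ascending missing count) fit a forest of the other columns on the rows
where the column is observed and re-predict its missing rows; sweep until
convergence.  Binary categorical columns are imputed by thresholding an
indicator regression at 0.5; higher-cardinality columns (not present in
the default schema) by one-vs-rest argmax, so imputed levels always come
from the observed level set.  Change statistics per sweep: numeric
Σ(curr−prev)²/Σcurr² and the fraction of categorical cells that switched,
both over originally-missing cells only.  Stopping: both statistics below
tolerance (1e-4 numeric, 0 categorical), or the numeric statistic first
increases (the previous sweep's matrix is returned — the established
stopping rule for this scheme), or `max_iter` (default 10; reported as
non-converged, never raised).  Imputation forests default to T = 100:
p+1 forests per sweep at T = 500 buys nothing measurable here.

Imputing the response alongside the predictors follows the scheme as
written, but leaks response information across rows if done before
cross-validation; `impute(..., exclude=("cbf",))` keeps the response (or
any column) out of both the imputed set and the predictor set.  The
default pipeline imputes once on the full matrix — the reading consistent
with the reported workflow — and the per-fold alternative is a caller
choice.

## Poiseuille TCD estimator

`cbf_tcd` evaluates CBF_TCD = πR²Mv/(2 cos θ): mean velocity is half the
centerline velocity under a parabolic profile, 1/cos θ corrects the
Doppler projection.  Schema units are cm/s, mm, g, degrees; `units="raw"`
bypasses conversion for formula-level work.  Two documented
ambiguities are left as configuration rather than resolved: (i) the
literal formula carries M in the numerator, so mapping it to the
per-100g scale of perfusion MRI has no unique dimensional reading — the
schema mode multiplies by one constant (60/230², calibrated at a 230 g
reference territory so typical inputs land in the physiological
20–60 ml/min/100g range), and the constant is an argument; (ii) the
angle factor is implemented exactly as 1/cos θ, although the source
discussion pairs "up to 40°" with "changes larger than 40%" while
1/cos 40° − 1 ≈ 30.5%.  Error propagation: a relative diameter error Δ
gives a relative flow error (1+Δ)² − 1 = 2Δ + Δ², so the ±0.4 mm
accuracy typical of MRA diameters (~17% at 2.4 mm) moves the estimate by
over a third; this quadratic sensitivity is the estimator's dominant
noise source and is tested as an exact identity.

## Leave-out experiments

Four designs, one forest per test row, with the exclusion sets asserted
disjoint from the training set on every run and the nesting chain
(exp4 ⊆ exp2, exp3 ⊆ exp1) property-tested exhaustively:

| design | excluded besides the test row |
|---|---|
| exp1_measurement | nothing |
| exp2_patient_side | same patient and side (all visits) |
| exp3_same_time | same patient and visit (both sides) |
| exp4_patient | the whole patient |

"Taken at the same time" is identified with sharing (patient, visit):
visits are the clock this data has.  Correlations are Pearson r with a
two-sided p from the t transform on n−2 degrees of freedom, reported
unfloored (the 2.2e-16 seen in standard software output is a reporting
floor, not a value); a seeded permutation p-value is available for
small-n verification.  `summarize` emits the experiment × (learning-set
range, r, p) table; `pooled_correlation` supports stratified reruns
(e.g. fitting healthy and diseased separately and pooling predictions).

**Null calibration.**  The calibration test generates cohorts in which
CBF moments are additionally pooled across groups and sides, because
under the published group-specific CBF means even the null regime carries
a real (group-mediated) signal of r ≈ +0.1 that a forest legitimately
finds; full exchangeability is the regime in which r is asymptotically
N(0, 1/√N) and spurious correlation can be distinguished from honest
group structure.

## Problem sizes and numerical choices

The test suite and the acceptance script run forests at T = 100 (m = 3,
n_min = 5) on the default 261-row cohort — the package's chosen
desk-scale configuration; r values stabilise to within ~0.01 between
T = 100 and T = 500 on these cohorts, while each leave-out experiment
(261 forests) runs in seconds instead of minutes.  All randomness flows
from explicit integer seeds through `numpy.random.SeedSequence` spawning;
identical seeds give bit-identical cohorts, forests, imputations and
correlations.  Degenerate inputs are defined behaviour: zero-variance
configs reproduce their means exactly, constant responses yield
single-leaf trees, complete matrices pass through imputation unchanged,
and correlation on fewer than 3 points or zero-variance vectors raises.

## Known limitations

* The generator's covariates are mutually independent given group, side
  and patient (no height–BMI–ICV correlation structure), and its
  missingness is MCAR; both are simplifications of clinical reality.
* Categorical imputation thresholds an indicator regression rather than
  fitting classification trees.
* The forest has no out-of-bag machinery, variable importances or
  surrogate splits — the explicit leave-out designs and the imputation
  module cover those roles here.
* Eq-level unit conversion in the flow estimator is calibrated, not
  derived (see above); treat absolute CBF_TCD levels as order-of-
  magnitude, relative comparisons as exact.
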