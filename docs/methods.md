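# Methods

## Scope and data model

The package analyses surface-enhanced Raman spectra of blood serum recorded
on a shared, uniform wavenumber grid (default 517–1913 cm⁻¹ with 1950
points, endpoints inclusive). Each spectrum belongs to a patient and each
patient to exactly one of two classes; several replicate spectra per patient
are the norm, and everything downstream treats the patient — not the
spectrum — as the statistical unit for resampling.

## Synthetic cohort generator

Real serum SERS cohorts of this kind are rarely public, so the generator is
a first-class, tested component that emulates the structure the analysis
relies on:

* **Band model.** Each of 15 serum bands (587–1657 cm⁻¹, with literature
  assignments such as uric acid at 638 cm⁻¹ and glycogen at 1051 cm⁻¹) is a
  unit-height Lorentzian — the natural Raman line shape — with a half-width
  at half-maximum of 8 cm⁻¹ and a fixed base amplitude between 0.3 and 0.9
  arbitrary units, roughly matching relative band prominences in serum.
* **Class effects.** Class membership acts as a per-band multiplicative
  factor. The default library encodes the respiratory-vs-referent
  directions: ×1.25 at 724, 947, 1051 and 1390 cm⁻¹ and ×0.75/×0.80 at 638
  and 1657 cm⁻¹ for the respiratory group, all other bands neutral.
* **Hierarchical noise.** Per patient, one multiplicative log-normal
  amplitude effect (σ = 0.15 on the log scale) — the simplest structure that
  correlates replicate spectra of one subject, which is precisely what the
  patient-wise split must respect. Per spectrum, a log-normal gain
  (σ = 0.10), additive i.i.d. Gaussian noise (σ = 0.02, about 2% of the
  strongest band), and a smooth background: a fifth-order polynomial in
  wavenumber rescaled to [−1, 1] with a positive ambient term, standing in
  for fluorescence.
* **Cohort shape.** Default classes are 41 "respiratory" and 103 "referent"
  patients at 3 spectra per patient (an optional per-patient jitter makes
  replicate counts uneven). `null_cohort` regenerates the identical cohort
  with every class factor forced to 1, giving an exact type-I-error harness.
* **Reproducibility.** A single integer seed spawns one child stream per
  patient, so cohorts are bit-identical across runs and stable under
  patient reordering.

What the generator does *not* emulate: cosmic-ray spikes, wavenumber
calibration drift between instruments, heteroscedastic shot noise,
correlated band co-variation from shared biochemistry, or substrate
batch effects. Passing tests therefore demonstrate that the pipeline's
logic is sound and calibrated, not that any particular clinical accuracy
is attainable on real serum; with the default (fairly clean) noise levels
the planted contrasts are easier to classify than real cohorts.

## Preprocessing chain

Fixed order per spectrum: crop to the closed 517–1913 cm⁻¹ window, then

1. **Savitzky–Golay smoothing** (window 15 grid points, polynomial order 1,
   derivative order 0), via `scipy.signal.savgol_filter` with fit-based edge
   evaluation (`mode="interp"`); the window is in grid points, the standard
   filter parameterization.
2. **Background removal** by the iterative modified-polynomial
   (peak-clipping) method at degree 15: fit, clip the working spectrum to
   min(spectrum, fit), refit, until the fit changes by less than a relative
   10⁻⁶ (L2) or 100 iterations. A single least-squares fit of that degree
   would be pulled into the peaks, which is why the iteration is the
   standard chemometric reading of "polynomial background removal". The
   polynomial is fitted in a Chebyshev basis on wavenumber rescaled to
   [−1, 1]; raw cm⁻¹ powers at degree 15 are numerically unusable. The
   least-squares projector is precomputed once per grid and reused across
   all spectra of a dataset.
3. **Standard normal variate**: per spectrum, subtract the mean and divide
   by the sample standard deviation (n−1 denominator); a constant spectrum
   is rejected as an error rather than silently zeroed.

Cropping keeps exactly the grid points inside the closed interval. SNV is
idempotent in isolation, but the full chain is not, and nothing assumes it
is.

## PLS-DA

Binary PLS1 with the response coded 0/1 and predictors only mean-centered
on the training set (spectra are already SNV-scaled per spectrum, so no
column autoscaling). For a univariate response the NIPALS weight vector is
closed-form per component (w ∝ Xᵀy, unit norm), so no inner iteration is
needed; components deflate X by t pᵀ. The regression vector is
b = W(PᵀW)⁻¹q, and prediction via b coincides with sequential
latent-variable reconstruction to floating-point accuracy. At full rank the
coefficients equal the minimum-norm least-squares solution, which the test
suite verifies against the pseudoinverse and against scikit-learn's NIPALS
implementation (used strictly as an independent oracle).

**Component selection.** The candidate count runs from 1 to
min(max_lv, 20, n_train − K) with max_lv = 15 by default, comfortably
containing the 5–7 components typical for this problem size. The
cross-validated RMSE per count is computed with patient-grouped,
class-stratified K-fold CV (K = 10 default); each fold is fitted once at the
largest count and truncated, which is algebraically identical to refitting
per count. The selected count is the *first local minimum*: the smallest
index whose RMSE drops below its left neighbor and does not exceed its
right neighbor; the first point qualifies when it does not exceed the
second, and a monotone nonincreasing curve yields its last (global-minimum)
point.

**Decision rule.** Label 1 iff score ≥ 0.5, ties to class 1. Posterior- or
distance-based rules used by some chemometrics packages are deliberately
out of scope; the threshold is configurable.

**VIP.** VIP_j = sqrt(p · Σ_a SSY_a (w_ja)² / Σ_a SSY_a) with
SSY_a = q_a² t_aᵀt_a. Weights are unit-norm, so Σ_j VIP_j² = p exactly —
the mean-square-1 identity asserted throughout the tests.

## Resampling protocol

For each of P divisions × T trainings (default 5 × 5 = 25 folds):

1. **Bootstrap balancing.** Patients of the larger class are sampled
   without replacement down to the smaller class's patient count (a
   with-replacement mode exists behind a flag for sensitivity analysis);
   within every retained patient a fixed number of spectra (default 3) is
   drawn, without replacement when the patient has enough replicates.
   Re-balancing happens fresh at every fold, so each fold sees a new
   bootstrap observation of the cohort.
2. **Patient-wise split.** One random patient per class is pinned to each
   side, the rest are shuffled, and the prefix whose spectra count lands
   nearest to train_fraction × total (default 0.8, ties toward the larger
   training set) becomes the training set. Train and test patient sets are
   disjoint by construction, and the split targets the *spectra* count
   while assigning whole patients.
3. **Fit and evaluate.** LV count by CV as above, then
   sensitivity/specificity/accuracy at the 0.5 threshold and ROC/AUC on the
   continuous scores, for both the training and the held-out set, plus the
   fold's VIP vector.

Aggregation is unweighted: mean, min and max per metric per set over all
folds, plus the element-wise mean VIP profile; `vip_band_report` then takes,
for each library band, the maximum mean VIP within ±window (default
10 cm⁻¹; window 0 reduces to a nearest-grid-point lookup) and ranks the
bands. Metric orientation: the positive class defaults to the class with
fewer patients — the disease group of interest in both supported designs —
and is recorded in every report.

Preprocessing is applied once before the fold loop: it is a per-spectrum
operation, so this is exactly equivalent to preprocessing inside each fold
and avoids redundant work.

## Metrics

Confusion counts with sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
accuracy = (TP+TN)/n; degenerate inputs (no positive or no negative truth)
raise instead of returning NaN. The ROC uses one operating point per
distinct score threshold plus the (0,0) sentinel and the trapezoidal AUC;
collapsing tied scores into single steps makes the trapezoid equal the
Mann–Whitney concordance probability with half-credit for ties, an identity
the tests check exactly.

## Numerical and design choices

* Baseline iteration stops on relative L2 change of the fit (10⁻⁶ default);
  the zero spectrum is handled by flooring the denominator.
* `cv_rmse` requires at least K patients; folds are dealt round-robin per
  class after shuffling, so class balance is preserved per fold.
* Random streams: every stochastic component takes a `numpy` Generator or
  an integer seed; the protocol spawns one child seed per fold, the
  generator one per patient; the CLI derives generation and protocol
  sub-seeds (< 2³¹) from a single `--seed`.
* Serialized models are plain JSON (arrays inline) so train/predict round
  trips are text-only and lossless at double precision.
* Output artifacts embed the seed and a SHA-256 digest of the effective
  configuration; identical seed + config reproduce identical bytes.

## Problem sizes

The test suite and the acceptance script run the full protocol at the
study-scale design (41 vs 103 patients, 1950-point grid, 25 folds — about
ten seconds on one core) and use coarser grids (60–400 points) and smaller
cohorts for unit-level checks, chosen so the whole suite completes in well
under a minute.

## Known limitations

* Binary PLS1 only — no multiclass PLS2, sparse or orthogonal variants.
* The balancing/split reconstruction targets the stated design (equal
  patient counts, fixed spectra draw, 80/20 by spectra count with whole
  patients); designs with strongly uneven replicate counts can land a few
  spectra away from the exact fraction.
* No despiking, wavenumber alignment, or instrument-transfer correction;
  inputs are assumed to share one calibrated grid.
* The null-calibration and signal-recovery guarantees are statements about
  the generator's statistical structure, not about clinical performance.
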