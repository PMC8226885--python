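# Methods

This note documents the models, algorithms, defaults and design choices
behind `nirselect`, in the spirit of a statistical software methods
appendix.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Calibration model

The calibration is single-response partial least squares (PLS1) on
mean-centered data: `ŷ = (x − x̄)·β + ȳ`.  Centering only, no
autoscaling — the default in NIR calibration, where pretreatment already
handles scale.  The core fit is a vectorized NIPALS loop with deflation
that returns β for every component count up to a cap in one pass
(`pls1_beta_path`); the selectors perform tens of thousands of small PLS
fits per run, and this path keeps them free of per-call overhead.  Two
independent cross-checks pin the implementation in the test suite: at
full rank a p-component PLS1 equals ordinary least squares, and on wide
data the coefficient equals a deflation-free oracle built from the Krylov
subspace span{X'y, (X'X)X'y, …} solved by QR/SVD.  scikit-learn's
`PLSRegression(scale=False)` is used as a third, external reference.

Degenerate inputs: a constant response raises; if the residual collapses
mid-path the path stops early and the last coefficient is reused for the
remaining counts.

## Model assessment (MCCV)

One external hold-out split (by default 50/195 of the samples) is fixed
from the seed *before* any selection; selectors and latent-variable (LV)
choice see calibration data only.  RMSECV pools squared validation errors
over N random re-splits of the calibration portion at the same
calibration fraction and divides by the total prediction count, so its
units are those of y.  Rc and Rp are Pearson correlations between
predicted and measured values (pooled MCCV validation predictions on the
calibration side; the single external prediction on the other) — the form
bounded in [−1, 1].  The LV count minimises pooled RMSECV over
1…`max_components` (default cap 20).  RPD divides the external set's
reference standard deviation (ddof = 1) by RMSEP; the qualitative bands
are > 2.5 excellent, [2, 2.5] very good, [1.8, 2) good, [1.4, 1.8) fair,
[1, 1.4) poor, < 1 very poor (2.5 itself rates "very good").

`MccvScorer` is the internal workhorse used by all selector search loops:
it freezes one set of calibration/validation splits so every candidate
channel subset is judged on the same draws (common random numbers), and
optimises the LV count along the PLS path per subset.  Without fixed
splits the comparison of thousands of subsets measures split luck as much
as subset quality.

## Preprocessing

Eight row-wise pretreatments, each a scikit-learn transformer: moving
average (truncated symmetric windows at the edges, default 11 points),
max/mean/range normalization, Savitzky–Golay first and second derivatives
(window 11, polynomial order 2, scaled by the mean wavelength step so
units are absorbance·nm⁻ᵒʳᵈᵉʳ; a global step keeps the operator linear on
a mildly non-uniform axis), MSC and SNV.  SNV uses the sample standard
deviation (ddof = 1), the dominant convention.  MSC fits per-spectrum
`(a, b)` minimising ‖x − a − b·ref‖² in closed form; the reference
defaults to the column mean of the data seen in `fit` and is stored, so
held-out spectra are corrected against the calibration reference (no
leakage).  Constant rows, zero divisors and |b| < 1e−12 raise with the
offending sample named.  Non-finite absorbance is rejected, never
imputed.

## Variable stability

`S_i = mean(β_i·)/(std(β_i·) + ε)` over M Monte-Carlo subsamples without
replacement (M = 100, n₁ = 0.8 n by default; ε = 1e−12 guards the
noise-free case, which is flagged `saturated`).  Selection compares |S|:
a strongly negative coefficient is as informative as a positive one.
The per-subsample fit uses **1 latent variable by default**: a 1-LV PLS
coefficient is proportional to the centered covariance of each channel
with y, so the ranking reflects each channel's own association with the
property.  Deeper fits concentrate weight on a few channels of a
collinear band and spread correction weight onto background channels,
which blurs the ranking; the LV count is exposed for sensitivity
analysis.

## VSCAA

Per iteration: (1) recompute stability on the survivors and split them
into useful/useless by weighted bootstrap sampling (p draws with
replacement, probability ∝ |S|; distinct draws are useful — the
equal-weight expectation is 1 − (1 − 1/p)ᵖ ≈ 0.632); (2) profile channel
frequencies over W = 500 random subsets of size P₁ = 0.5 p, keeping the
best 10 % of submodels **by validation RMSE on one shared random hold-out
split** — in-sample ranking would reward interferent-rich subsets that
fit the calibration set but predict poorly; (3) shrink to the decay
target, removing low-frequency useless channels first and cutting into
the useful set (by low |S|) only when the target drops below its size;
ties break on the other criterion, then on higher channel index;
(4) score survivors with the shared fixed-split MCCV scorer (10 splits,
LV-optimised).  After N = 50 loops the minimum-RMSE iteration supplies
the selection; the full per-iteration audit trail is retained.

The decay constants follow the CARS convention, α = (p/2)^{1/(N−1)},
k = ln(p/2)/(N−1), so r₁ = 1 (nothing eliminated on the first loop) and
r_N·p = 2.  r_i is a retained *fraction* of the initial channel count;
reading it as a raw count would retain one variable at iteration 1.  A
literal `as_printed` variant (k divided by a further N − 1) is kept
behind a flag for audits; it eliminates almost nothing
(r_N ≈ 0.985 for p = 397, N = 20) and is not the default.

All Monte-Carlo stages of one run draw from a single seeded generator
stream, so one integer reproduces the whole run.

## Comparison selectors

* **SiPLS** — contiguous near-equal intervals (widths differ by ≤ 1,
  earlier intervals take the extra channel; 19 intervals over 397
  channels gives widths {20, 21} and 4-interval unions of 80–84
  channels); exhaustive search over interval combinations scored by
  fixed-split MCCV RMSE; a guard refuses more than 10⁶ combinations.
* **SPA** — successive projections chains from every start channel
  (centered columns; the next channel maximises the residual norm after
  projecting out the chosen span, so exact duplicates can never both be
  chosen); chain and size picked by MCCV RMSE.
* **GA** — binary chromosomes over channels, tournament selection (size
  2), uniform crossover (rate 0.8), per-bit mutation (0.01), elitism of
  one, fitness = −MCCV RMSE with memoisation; operator suite follows
  standard wavelength-selection GA practice.
* **BOSS** — uniform initial weights; each round draws `n_submodels`
  weighted-bootstrap channel sets, keeps the better-RMSE half, rebuilds
  weights from the kept submodels' normalised |β| (weights sum to 1 every
  round), and continues while the nonzero-weight support shrinks; the
  minimum-RMSE round's support is returned.

Selectors compose through `chain_select`; composed indices always refer
to the original axis, and every stage sees only its predecessor's
survivors.

## Taste index

TI = SSC/TA, and the weighted transform
nV_TI = TA·(P_TA/100) + TI·0.119·(P_TI/100) with default weights 90/10.
The 0.119 factor is a fixed constant of the transform, numerically close
to a typical mean TA (which makes the second term roughly SSC-scaled); it
is exposed in `TasteIndexParams` for transparency rather than derived.
With mean TA 0.1194 % and mean TI 83.08 the transform gives 1.0961.

## Synthetic test bed

The generator emulates fruit diffuse-reflectance NIR absorbance in
1000–2300 nm (400 uniform channels by default): a fixed rising background
with two broad humps (the large baseline offset typical of diffuse
reflectance), three informative Gaussian bands at 1450/1780/2150 nm
(width 20 nm) whose amplitudes scale linearly with a latent property
drawn uniformly from 8–12 (°Brix-like), ten concentration-independent
interferent bands with per-sample random amplitudes, a small random
polynomial baseline, per-sample multiplicative gain and additive offset,
and white noise with SNR 20 (largest band span / noise sd) rising toward
both axis ends.

Three features were chosen deliberately, to reproduce on synthetic data
the qualitative behaviours that make wavelength selection worthwhile on
real spectra:

* **Band-centre jitter (8 nm sd).**  Real NIR peak positions wander with
  temperature and matrix effects.  Jitter makes retaining a *whole* band
  — shoulders included — genuinely better than cherry-picking its core
  channels, because the band integral is shift-invariant while individual
  channels are not.
* **Noisy axis ends (noise ×≈7 at the extremes, decaying over 60 nm).**
  Compact NIR detectors degrade at their range limits; this is the
  classic reason edge regions are trimmed or selected away.  These
  channels genuinely hurt a full-spectrum model, giving selection a real
  target.
* **Interferents clear of the analyte bands.**  The interferent centres
  keep ≈ 3 widths away from the (jittered) analyte band regions.  When
  interferent tails overlap analyte bands, a full-spectrum model gains a
  real advantage from deconvolving them, which is a different scientific
  regime than the band-selection problem posed here.

Residual scatter is small (gain sd 0.003, offset sd 0.001) — the scenario
represents spectra after competent scatter correction; the SNV/MSC
operators are exercised against explicitly scaled-up scatter in the test
suite instead.  The ground-truth "informative" channel set is everything
within ±2 band widths of an analyte band centre; recovery is recall
against that union.  What passing tests show: the selectors recover
planted, approximately band-shaped, linearly acting signal under
scatter-corrected, moderately interfered conditions.  What they do not
show: performance under strong nonlinear matrix effects, calibration
drift between batches, or instrument transfer — none of which the
generator attempts.

## Problem sizes and determinism

Default study conditions: n = 200 samples (calibration fraction 145/195),
p = 400 channels, M = 100 stability subsamples, W = 500 variable spaces,
N = 50 VSCAA loops, 100 MCCV repeats for reported figures and 10
fixed splits for internal selector scoring.  Recovery statistics are
medians over ten scenario draws.  Every stochastic component accepts a
seed; identical seeds give bit-identical results, and per-stage seeds in
the pipeline derive from one master seed via `SeedSequence`.

## Known limitations

* The frequency profile's null distribution is not channel-uniform
  conditional on a dataset: the best submodels genuinely concentrate on
  channels spuriously correlated with y.  Uniformity holds only
  marginally across datasets, and only approximately at feasible
  replication; the suite checks a bounded-deviation form.
* The Step-6 argmin is only as sharp as the internal RMSE trajectory;
  on data where elimination yields no internal gain the selector
  legitimately returns (nearly) the full spectrum.
* `as_printed` decay exists for audit only; it barely eliminates.
* PLS2 (multi-response) and nonlinear calibration are out of scope.
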