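# Methods

This note documents the models, algorithms and numerical choices behind
`oilblend`, and what the synthetic study design does and does not
establish about real measurements.

## The measurement model and the synthetic generator

A sample is a binary blend of a genuine oil (sesame or rapeseed) with
soybean oil at genuine-oil fraction `r ∈ [0, 1]`. The generator models the
clean reflectance of a blend as linear in `r`:

    x(λ) = r·g(λ) + (1 − r)·s(λ)

with `g`, `s` parametric endmember spectra (a smooth logistic baseline
rising from a dark visible band to a bright NIR plateau, shared NIR
absorption troughs near 930/1210/1450 nm, plus per-oil Gaussian features:
one broad visible trough for soybean, two narrow visible troughs for
rapeseed, a slow featureless visible rise for sesame). Structure imposed on
the defaults: the visible band (400–700 nm) carries the largest
between-oil separation with soybean the brightest oil; soybean also
out-reflects both genuine oils over 720–1700 nm, so blend reflectance
there rises monotonically with the soybean fraction; above ~1700 nm all
endmembers coincide within 0.01 (the "flat band"), implemented by
windowing every per-oil offset to decay before 1700 nm. Evaluated
reflectance stays within [0, 1.2] on the default 350–2500 nm, 1 nm grid.

Linearity of blend reflectance in volume fraction is an *assumption*, made
because it is the simplest model consistent with the monotone trends the
analysis exploits and because it makes ground truth analytic. Real blend
optics (and real instrument response) need not be linear; none of the
pass/fail results here certify behaviour on measured spectra.

Measurement artefacts are (i) a per-sample affine scatter distortion
`x → b·x + a` with `b = exp(N(0, σ_mult²))`, `a ~ N(0, σ_add²)` — the
particle-scatter effect SNV and MSC exist to remove — and (ii) per-point
white noise `N(0, σ_white²)`. Defaults `σ_mult = 0.05`, `σ_add = 0.01`,
`σ_white = 0.002` put raw-spectrum models visibly below the
scatter-corrected ones while keeping the corrected pipelines in the
high-accuracy regime the method targets. Negative distorted values are
clipped at zero (with a logged count); at the default noise scales
clipping never triggers, so the affine-recovery properties hold exactly.

Randomness contract: each sample's draws come from
`numpy.random.default_rng([seed, sample_index])` (PCG64 via SeedSequence),
making a dataset a pure function of the seed, independent of generation
order and platform.

The default design enumerates, per replicate group and case, the ratios
0, 0.1, …, 1.0 — per group that is 9 adulterated sesame blends,
9 adulterated rapeseed blends, and 4 pure oils (one sesame, one rapeseed,
and one soybean per case), hence 110 samples over five groups. The
qualitative task labels each case's samples pure genuine (r = 1),
low-adulterated (0.6 ≤ r ≤ 0.9), high-adulterated (0.1 ≤ r ≤ 0.4) and a
shared pure-soybean class (r = 0) — seven classes; the ten r = 0.5 blends
are excluded as practically rare.

## Pretreatments

All pretreatments are fit/apply pairs; only MSC learns anything (its
reference spectrum), and it learns it from the calibration partition only,
to keep prediction folds untouched.

- **SNV**: `(x − mean(x)) / sd(x)` per spectrum, sample (n−1) standard
  deviation. Exactly invariant (up to float rounding ~1e−12) under
  `x → b·x + a`, `b > 0`. A constant spectrum has no SNV transform and
  raises.
- **MSC**: least squares of `x = a + b·ref` over wavelengths, output
  `(x − a)/b`; `|b|` below 1e−8 (spectrum uncorrelated with the reference)
  raises naming the sample. With a fixed reference, a distorted spectrum
  `b·x + a` maps to exactly the same output as `x` — MSC restores clean
  spectra *up to an affine map of the reference*; it does not literally
  invert the distortion unless the clean spectrum lies in the affine span
  of the reference.
- **Savitzky–Golay**: `scipy.signal.savgol_filter`, default window 11
  points / order 2 on the 1 nm grid. Edges use scipy's polynomial
  interpolation mode: the filter then reproduces any degree ≤ 2 polynomial
  exactly at every point, including the boundaries, which mirror padding
  would break.
- **Wavelet shrinkage**: PyWavelets, default Daubechies-4, level 4, soft
  universal threshold `σ·sqrt(2 ln n)` with `σ` estimated per spectrum as
  `MAD(finest detail)/0.6745`. A zero threshold (e.g. a noiseless
  spectrum) skips shrinkage entirely, giving perfect reconstruction.

## PLS, VIP and model-order selection

Single-response NIPALS is deterministic: each component's weight vector is
the normalised covariance direction `X'y` of the deflated data — no
iteration, no random start. Scores are mutually orthogonal; with as many
components as the centred rank, the regression vector coincides with the
minimum-norm OLS (pseudoinverse) solution, which is the main correctness
oracle. `B = W (P'W)^{-1} q` is evaluated with a dense solve of the small
A × A system. If the covariance is exhausted early (numerically zero
`X'y`), the achieved component count is used with a logged warning.

X columns are centred but not variance-scaled — reflectance shares units
across wavelengths, so scaling would inflate noise-only wavelengths; a
caller wanting scaled behaviour can standardise beforehand. The
latent-variable count is chosen by 10-fold RMSECV over 1..15 (one max-order
fit per fold, truncated to every smaller order), ties broken toward the
smaller count so exact low-rank data never gets extra components.

VIP uses the standard statistic with `SS_a = q_a² t_a't_a`; the squared
scores always average to 1, which every fitted model asserts in tests.

## Wavelength selection

- **PCA loadings** (unsupervised): score each wavelength by its largest
  absolute loading over the leading principal components (default: as many
  components as explain 99% of variance) and keep the top k.
- **VIP**: threshold 1.0 by default (the "average importance" cutoff);
  a top-k mode exists for fixed-cardinality comparisons.
- **SPA**: classic successive projections — grow chains by maximal
  residual norm after Gram–Schmidt deflation, one chain per candidate
  start column; score every prefix of length k_min..k_max by 5-fold CV
  least-squares RMSE; return the best prefix. All-starts SPA is
  O(k·n·p²); the default restricts candidates to min(p, 50) evenly spaced
  start columns, which preserves the algorithm's character at tractable
  cost and is overridable to all p starts. The deflation is implemented
  as a rank-1 update and verified column-for-column against an explicit
  QR-based reprojection oracle.
- **CARS**: N = 50 Monte-Carlo runs, 80% row subsampling, inner PLS with
  up to 10 latent variables (a fixed cap — re-selecting the order inside
  every run would multiply cost for no measurable benefit on this data).
  Retention follows the exponentially decreasing schedule
  `r_i = a·e^{−k·i}` with `a`, `k` fixed by the endpoint conditions
  "retain all p at run 1, retain 2 at run N" — the only parameter-free
  closure of exponential decay. After coefficient-ranked truncation,
  adaptive reweighted sampling (draws with replacement, probability
  ∝ |B_j|) fixes the run's subset; each subset is scored by 10-fold
  RMSECV on the full calibration data and the arg-min subset wins. A
  subset collapsing below two wavelengths falls back to the top two
  weights with a logged warning; a final check warns (Python warning) if
  the winning subset scores worse than the full-wavelength model.

Ranking ties anywhere break toward the lower wavelength index, making
every selector reproducible bit-for-bit under a fixed seed.

## Cross-validation and metrics

Ten folds, sizes differing by at most one, each sample predicted exactly
once; folds are stratified (by ratio for regression, by class for
classification) so every fold spans the response range. Aggregates are
arithmetic means of per-fold metrics (asserted to 1e−12). Metrics are the
field's standard accuracy `m_k/n`, `R² = 1 − SS_res/SS_tot` and
`RMSE = sqrt(SS_res/n)`; R² on a constant truth vector is undefined and
raises rather than returning a sentinel.

`leakage_mode="fold_safe"` (default) fits pretreatment, selection and
model inside each calibration fold. `"pooled"` fits pretreatment and
selection once on all samples before splitting — a protocol some studies
use, provided for comparability; the mode is recorded in the result's
provenance snapshot. Regression targets the genuine-oil fraction;
`invert_target` switches to the soybean (adulterant) fraction, which only
mirrors predictions and leaves RMSE/R² unchanged.

Reference models are scikit-learn estimators behind thin adapters: SVC /
SVR (RBF, gamma = 1/p), RandomForest (500 trees, seeded), KNeighbors
(k = 5). The SVM margin penalty defaults to C = 1000: SNV-corrected
spectra live on a small per-feature scale, and with C ≈ 10 the RBF
machine underfits to the point of ~0.70 calibration accuracy, whereas the
method's operating regime has saturated calibration accuracy. PLSR is the
native NIPALS implementation; sklearn's `PLSRegression` appears only as
an independent cross-check in the test suite.

Per-wavelength Pearson correlation uses the closed-form r with a
two-sided t-test (n − 2 df); constant columns yield NaN with a logged
count rather than aborting. No multiplicity correction is applied by
default (raw per-wavelength r and p are the quantities of interest);
callers can post-process with any FDR procedure.

## Problem sizes and determinism

The default test suite and the acceptance script run the full 110 × 2151
design; the heaviest piece (fold-safe CARS inside 10-fold CV, both cases,
five seeds) completes in well under a minute thanks to the iteration-free
PLS1 core. All stochastic stages (generator, folds, CARS, RF) derive from
explicit integer seeds; fixed seeds give bit-identical outputs.

## Known limitations

- Endmember shapes are qualitative stand-ins; amplitudes and peak
  positions are not fitted to any measured oil spectrum.
- Linear blending and affine scatter are assumptions; wavelength-dependent
  scatter, instrument drift, temperature effects and detector nonlinearity
  are not modelled, so the pretreatments face exactly the distortion class
  they are designed for — the synthetic results are a best case.
- The 50-start SPA default is an approximation of exhaustive-start SPA;
  with highly structured spectra the exhaustive variant can find different
  chains.
- With the default endmembers the NIR correlates negatively with the
  genuine-oil ratio wherever it is informative; no wavelength with a
  strong positive correlation exists above 1700 nm because the flat band
  carries no compositional signal by construction.
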