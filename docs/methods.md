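# Methods

`chronossa` analyses epoch-based actigraphy (nonnegative movement counts
per fixed epoch, typically 1 min over 7 continuous days) at three time
scales: the average circadian cycle (cosinor), rest-activity
fragmentation across resampling scales (the IV(P) curve), and a
data-adaptive decomposition (singular spectrum analysis, SSA) that
yields both day-to-day circadian parameters and the power-law structure
of the ultradian variance spectrum.  A synthetic cohort generator
provides ground-truth data for every stage.

## Cosinor rhythmometry

The model is `y(t) = M + A cos(2πt/T + φ)` with mesor `M`, amplitude
`A ≥ 0`, period `T` and phase `φ`, fitted by linear least squares in the
`(M, a, b)` parameterisation `y = M + a cos(ωt) + b sin(ωt)`, which is
the exact global optimum for fixed `T` (no iteration, no local minima).
Time is measured in minutes after the midnight preceding the recording,
so the clock position of the fitted maximum — the acrophase `φ₀`,
reported in degrees after midnight (360° = 24 h) or hh:mm — is
comparable across subjects; `φ` itself depends on the recording start
and is reported but not interpreted.  Goodness of fit is
`R² = 1 − Var(e)/Var(x)`.

The period is chosen per subject by scanning a grid (default
1320–1560 min in 1-min steps, covering the observed ±2 SD spread around
24 h with margin) and keeping the `T` that maximises the fitted
amplitude, the field's convention for rest-activity data.  Two caveats
are deliberate:

* Over a finite record with a non-integer number of cycles, spectral
  leakage biases the amplitude-maximising `T` a few minutes above the
  true period even for noise-free data (the residual-sum criterion,
  available as `scan_criterion="ssr"`, is exact there).  The bias is
  well below the between-subject period SD (~20 min).
* Ties are broken toward 1440 min, the physiologic prior.

A period deviation `ΔT = T − 1440` accumulates day after day; the
implied acrophase trajectory is the line with slope `ΔT · 360/1440`
degrees per day (+3 min → +0.75°/day, −24 min → −6°/day).

Mean acrophases are arithmetic means of values unwrapped around the
subject mean, not circular means: acrophases cluster mid-afternoon, far
from the wrap point, so the simpler convention is safe; it would not be
for populations peaking near midnight (documented limitation).

## Intradaily variability IV(P)

Classic IV is the variance of the first differences of the series
(numerator divisor `N−1`) over the variance of the series (divisor
`N`), traditionally after resampling to 60-min bins.  Treating the
resampling interval `P` as a parameter gives a curve; because numerator
and denominator each depend on `P`, the curve used here divides by the
variance of the *original* series, constant in `P`, so IV(P) is a
single-valued function of scale.  The legacy normalisation (divide by
`Var(X_P)`) remains available for comparison.

Resampling uses bin *means*, keeping `X_P` on the counts/min scale of
the raw series so that the fixed denominator is commensurable across
`P`; bin sums would inject a `P²` factor into the curve's shape.
Trailing samples that do not fill a bin are dropped with a warning
rather than padded, avoiding an artificial step in the differences.
The default grid is ~40 log-spaced values over 1–600 min plus the
canonical `P = 60`, covering both the circadian maximum near
`P ≈ 500 min` and the sub-hour region where fragmented rhythms add
variance.  IV is invariant under additive shifts and, in both
normalisations, under rescaling of the counts.

## Singular spectrum analysis

SSA embeds the series in a `K × L` Hankel trajectory matrix (window
`L`, `K = N − L + 1`), takes its SVD `X = Σ σ_k u_k v_kᵀ`, and maps
each rank-1 term back to a series `g_k(n)` by averaging anti-diagonals,
giving the exact additive decomposition `x(n) = Σ σ_k g_k(n)`.
Components are stored unit-normalised with the singular values as
separate weights; partial variances `λ_k = σ_k²` sum to the squared
Frobenius norm of the trajectory matrix.  Exactness (reconstruction to
< 1e-8 relative, energy bookkeeping to 1e-8) is enforced by tests on
random series.

Choices:

* **Window** `L` = one circadian period — 1440 min (1440 samples at
  1-min epochs, 288 at 5-min).  Periodicities up to ~`L` are resolved;
  slower structure is absorbed into the trend.  As `L → N/2` the
  decomposition converges to Fourier analysis (tested on a pure
  sinusoid: ≥ 99.9% of variance in one component pair).
* **Truncation**: `r_max` caps the number of components returned; the
  scaling fits only use ranks up to `log₁₀k = 3`, so `r_max = 1000`
  suffices for week-long 1-min series.  Exact-reconstruction guarantees
  apply at full rank.
* **Component identification**: the leading component is the trend; the
  circadian rhythm appears as a near-degenerate pair (the data-adaptive
  analogue of a sine/cosine pair), by default components 2–3.  An
  auto-detector scans for the first pair with
  `|λ_k − λ_{k+1}|/λ_k < 0.2` whose mean periods fall within 20% of
  1440 min, falling back to (2, 3) — useful when the trend splits.
* **Mean period** of a component is twice the mean spacing between zero
  crossings of the mean-centred series (equivalent to `2NP/#crossings`
  away from the edges but unbiased when the series starts or ends on a
  crossing); components with fewer than two crossings are labelled
  trend.  On noisy data this is an order-of-magnitude label, not a
  precise frequency estimate: noise leakage perturbs individual
  components' counts by ±20% while the circadian pair's mean stays
  accurate.
* **w-correlation** uses the standard weights `w_n = min(n, L, K,
  N−n+1)` (the multiplicity of each sample in the trajectory matrix) to
  quantify separability between reconstructed components.

## Day-to-day circadian parameters

The trend plus circadian-pair reconstruction is read day by day — a
procedure this package makes explicit, since reading per-day values off
the reconstruction admits several conventions:

* acrophase_d: clock position of the d-th local maximum of the
  circadian series, maxima constrained to be ≥ 18 h apart so ultradian
  leakage cannot create spurious daily peaks; values unwrapped so drift
  appears as a trend, not ±360° jumps;
* period_d: spacing between successive maxima (D−1 values);
* amplitude_d: half the max−min range between the two minima bracketing
  maximum d;
* mesor_d: mean of the trend component over calendar day d.

Maxima within 2 h of the series boundary are flagged: diagonal
averaging distorts the reconstruction near the edges (edge-day
acrophases are good to ~5° where interior days reach ~2° on noise-free
data).

Summary statistics per parameter use population (divide-by-n) moments,
consistent with the variance conventions above: SD, CV = SD/mean,
skewness `m₃/m₂^{3/2}` and Pearson kurtosis `m₄/m₂²` (Gaussian → 3;
a linear trend added to Gaussian noise spanning 4 SD lowers it to
14.2/2.333² ≈ 2.61; a uniform sample gives 1.8; 1 is the analytic lower
bound).  Kurtosis of day-to-day acrophases distinguishes Gaussian
jitter (≈3) from drift-dominated, platykurtic behaviour (<3).

**Known shrinkage.** The circadian pair is a rank-2 projection: rapid
day-to-day modulation of phase or amplitude puts part of its energy
into higher-order components, so the day-to-day SD/CV read from the
pair is attenuated — negligible for moderate variability (a 7.5°
acrophase SD is recovered within ~10%), growing to ~30% for large
variability (15° and beyond, amplitude CV ≳ 0.2).  Recovered
variability is monotone in the injected value throughout.  Group
*contrasts* in these statistics are preserved; absolute values are
conservative.

The SSA `R²` uses the cosinor formula with `y = trend + circadian`; it
exceeds the cosinor `R²` on any series with genuine day-to-day
variability, because the cosine can only describe the average cycle.

## Ultradian scaling

Ordered fractional partial variances `λ_k/λ_tot` (the scree diagram)
are fitted by ordinary least squares in log₁₀–log₁₀ coordinates, with
the exponent `γ = −slope`; ranks are 1-based and include trend and
circadian components, so the ultradian tail starts at `k = 4`.  No
binning is applied — the rank grid is already dense in log space over
the fitted decades.  Ranges (in `log₁₀k`): single law [0.78, 3.0],
crossover pre-range [0.8, 1.5] and post-range [1.6, 2.0], band
[1.4, 1.6].  With `L` fixed at 1440 min the band maps to components
with mean periods of roughly 70–115 min regardless of epoch, i.e. the
basic rest-activity cycle (BRAC) scale; `band_to_frequency` reports
the actual per-component period range.  A 1/f-like series shows one
exponent `γ ≈ 1` across the whole range; excess band variance breaks
the law into `γ₂ > γ₁`.  Exponent recovery is verified by Monte-Carlo
(γ ∈ {0.5, 0.85, 1, 1.02, 1.5}, 10% multiplicative noise, 200 seeds,
|bias| < 0.05); the fit is invariant to overall scaling of λ.

## Cohort statistics

Two-group comparisons of per-subject parameters use the Kruskal-Wallis
rank test with tie correction and a χ²(1) p-value (an exhaustive
permutation null is available for very small groups).  The minute-wise
mean 24 h profile averages each subject over days (subjects, not days,
are the replication unit) and tests each minute-of-day bin at raw
α = 0.05 with *no* multiplicity correction — a deliberately liberal
convention that flags rest-to-wake and wake-to-rest transition bands;
a Benjamini-Hochberg flag is provided for a corrected view.
Cosinor-vs-SSA agreement is the per-subject Pearson `r` and Spearman
`ρ` between the cosinor model series and the SSA trend + circadian
reconstruction.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes —
not real actigraphy physiology.  Per subject:

    x(t) = clip( M_s + A_d cos(2π(t − m₀ − δ_d)/T) + u(t), 0, ceiling )

* `M_s ~ N(216, 56²)` counts/min across subjects; amplitude
  178 counts/min with day-to-day CV 0.28; acrophase 232° (15:28) with
  26° day-to-day SD; `T = 1440` min; ceiling 3000 counts/min.  These
  defaults are the control-like study conditions; an insomnia-like
  group raises the acrophase (253°) and switches the ultradian mode.
* Per-day phase offsets are drawn i.i.d. (no random walk — systematic
  drift is injected via `period_minutes` instead), anchored at each
  day's peak and linearly interpolated between peaks so the injected
  acrophase is exact at the peak and the phase is continuous across
  midnight.  Per-day amplitudes are piecewise constant per calendar
  day; the midnight step is small because the cosine is far from its
  peak there.
* `u(t)`: spectrally shaped Gaussian noise at 300 counts/min RMS.  In
  `one_over_f` mode the amplitude envelope is `f^(−1/2)` (power 1/f) at
  ultradian frequencies, plateaued below the circadian frequency so the
  stochastic term does not add multi-day drift on top of the modelled
  mesor.  In `brac90` mode a band-limited oscillation (Gaussian
  spectral envelope centred on the 90-min line, fractional width 0.2,
  spanning periods ≈ 70–120 min) is added with variance
  `brac_relative_power` (default 0.3) times the 1/f variance — an
  oscillation coherent over a few cycles that lands, as intended, in
  the scree band around `log₁₀k = 1.5` rather than outranking the
  circadian pair.  A perfectly coherent sine would instead appear as a
  single high-rank pair; the bandwidth is what localises the bump at
  the BRAC ranks.
* Optional multiplicative burst noise (off by default) mimics "spiky"
  intermittency; it is user-set, not calibrated, since no quantitative
  model of it exists.
* Counts are nonnegative reals by default so noise-free parameter
  recovery is exact to numerical precision; `integer_counts=True`
  rounds to the integers a device would report (adding ~0.3-count
  quantisation noise).

What the generator does **not** emulate: sleep-stage architecture,
nonwear intervals, device transduction, activity-dependent
(multiplicative) noise, or the heavy right skew of real counts.  Two
visible consequences: the clip at 0 of symmetric noise during the night
trough biases fitted mesors up (~+60 counts/min at the default noise
level) and amplitudes down, as rectification does in real data too; and
absolute `R²` values are higher than in field recordings.  Passing
tests therefore demonstrate correctness of the estimators and the
direction and detectability of group effects, not field-realistic
effect sizes.

## Problem sizes and numerics

Cohort-level analyses (group recovery, BRAC discrimination) run on
7-day series at 5-min epochs: `N = 2016`, window 288 samples = 1440 min,
so the rank-to-period mapping of the scree bands is identical to the
1-min condition while the trajectory SVD is ~100× cheaper.
Single-subject checks (the control scree exponent, SSA vs cosinor `R²`)
run at the full 1-min resolution (`N = 10080`, `L = 1440`,
`r_max = 1000`).  SVD is LAPACK `gesdd` via NumPy on the full
trajectory matrix; diagonal averaging of rank-1 terms uses FFT
convolution (`conv(u_k, v_k)` divided by the diagonal weights).
Degenerate inputs fail loudly: constant series are rejected wherever a
variance ratio is undefined; zero-norm components get w-correlation 0
with a forced unit diagonal; scree ties keep the SVD order.
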