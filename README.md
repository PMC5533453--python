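# chronossa

Multiscale analysis of circadian and ultradian rest-activity rhythms in
actigraphy time series — for chronobiologists, sleep researchers and
biostatisticians working with wrist-worn movement-count recordings
(counts per 1-min epoch, continuous day-and-night, typically one week).

Rest-activity disruption in conditions such as insomnia is often subtle:
average circadian parameters barely move while the *day-to-day*
variability of the rhythm and the *ultradian* (sub-24 h) variance
structure change measurably.  `chronossa` implements the three
complementary analyses needed to see this, plus a synthetic cohort
generator with known ground truth:

* **Cosinor rhythmometry** — least-squares fit of
  `y(t) = M + A cos(2πt/T + φ)`, with a per-subject period scan that
  maximises the fitted amplitude, and the acrophase `φ₀` (clock time of
  the fitted maximum, 360° = 24 h after midnight) as the primary phase
  output.
* **Intradaily variability IV(P)** — `IV(P) = Var(X′_P)/Var(x)`, the
  variance of the first differences of the series resampled to interval
  `P`, normalised by the constant variance of the original series, as a
  function of `P`.
* **Singular spectrum analysis (SSA)** — exact, data-adaptive
  decomposition `x(n) = Σ_k σ_k g_k(n)` via Hankel embedding
  (window `L` = 1440 min), SVD and diagonal averaging.  The leading
  component is the trend (mesor), the near-degenerate pair (2, 3) is
  the circadian cycle — read day by day for per-day mesor, amplitude,
  acrophase and period with SD/CV/skewness/kurtosis summaries — and the
  ordered fractional partial variances `λ_k/λ_tot` of the ultradian
  tail (`k ≥ 4`) follow a power law `λ_k ∝ 1/k^γ`, fitted with single
  and crossover (`γ₁`, `γ₂`) exponents and the variance share of the
  60–90-min band.
* **Cohort statistics** — Kruskal-Wallis group comparisons, minute-wise
  mean 24 h profiles with significance intervals, and cosinor-vs-SSA
  agreement (Pearson `r`, Spearman `ρ`).

`CosinorRegressor` and `SingularSpectrum` are scikit-learn estimators
(`fit`/`predict`/`transform`, `get_params`); module-level functions wrap
them for one-line use.  See `docs/methods.md` for the full model
description, conventions and known limitations.

## Worked example

```python
import numpy as np
from chronossa import (CohortSpec, generate_subject, scan_period, decompose,
                       ComponentGrouping, ssa_r_squared)
from chronossa.circadian import circadian_reconstruction, daily_parameters
from chronossa.scaling import single_fit
from chronossa.ssa import find_circadian_pair

spec = CohortSpec(seed=11)          # control-like subject, 7 days at 1-min epochs
s = generate_subject(spec, 0)

T, fit = scan_period(s)             # cosinor with amplitude-maximising period
print(f"cosinor: T={fit.T:.0f} min  M={fit.M:.0f}  A={fit.A:.0f}  "
      f"acrophase={fit.acrophase_deg:.0f} deg ({fit.acrophase_hhmm})  R2={fit.r_squared:.2f}")

dec = decompose(s, L=1440, r_max=1000)        # SSA, 24-h window
pair = find_circadian_pair(dec)
trend, circ = circadian_reconstruction(dec, ComponentGrouping((0,), pair))
daily = daily_parameters(trend, circ, s.epoch_minutes, s.start_clock)
print("daily acrophase (deg):", np.round(daily.acrophase_deg, 1))
print(f"SD(phi0)={daily.summaries['acrophase_deg']['sd']:.1f} deg  "
      f"CV(A)={daily.summaries['amplitude']['cv']:.2f}  "
      f"SSA R2={ssa_r_squared(s, trend, circ):.2f}")

sf = single_fit(dec.partial_variances)        # ultradian scree power law
print(f"scree power law: gamma={sf.gamma:.2f} (r2={sf.r_squared:.3f})")
```

Output:

```
cosinor: T=1425 min  M=269  A=190  acrophase=242 deg (16:08)  R2=0.24
daily acrophase (deg): [220.3 202.3 256.2 249.3 227.5 220.  189.5]
SD(phi0)=22.0 deg  CV(A)=0.20  SSA R2=0.36
scree power law: gamma=1.03 (r2=0.999)
```

Reading it: the average cycle peaks mid-afternoon (acrophase 242° =
16:08) but the cosine explains only 24% of the variance; the SSA
trend + circadian reconstruction follows the day-to-day wandering of the
peak (per-day acrophases spanning ~190–256°, SD 22°) and raises `R²` to
0.36; the ultradian scree tail decays as `1/k^1.03` — the 1/f-like
signature of healthy, multiscale activity.  An insomnia-like subject
(`ultradian_mode="brac90"`) instead shows excess variance in the scree
band mapping to 60–90-min periods and a crossover `γ₂ > γ₁`.

## Command line

```bash
chronossa simulate --config cohort.yaml --out cohort/      # synthetic cohort
chronossa cosinor  --in cohort/manifest.csv --out cosinor.csv
chronossa iv       --in cohort/manifest.csv --out iv.csv
chronossa ssa      --in cohort/control_000.csv --L 1440 --rmax 1000 --out-prefix s0_
chronossa circadian --in cohort/control_000.csv --out daily.csv --summary summary.csv
chronossa scaling  --scree s0_scree.csv --out scaling.csv
chronossa cohort   --manifest cohort/manifest.csv --out report/
```

Subject files are plain CSV (`timestamp`, `counts`); cohorts are
described by a manifest CSV (`subject_id`, `group`, `file`).

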