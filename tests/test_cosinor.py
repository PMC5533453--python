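import numpy as np
import pytest

from chronossa import CosinorRegressor, fit_cosinor, scan_period, acrophase_clock
from chronossa.cosinor import acrophase_trajectory, default_period_grid
from conftest import make_series


def test_exact_model_data(cosine_series):
    fit = fit_cosinor(cosine_series, 1440.0)
    assert fit.M == pytest.approx(216.0, abs=1e-8)
    assert fit.A == pytest.approx(178.0, abs=1e-8)
    assert fit.acrophase_deg == pytest.approx(232.0, abs=1e-8)
    assert fit.acrophase_hhmm == "15:28"
    assert fit.r_squared == pytest.approx(1.0, abs=1e-12)


def test_noise_does_not_bias_linear_fit(cosine_series):
    """Least squares is linear: fit(signal + noise) = fit(signal) + fit(noise)."""
    rng = np.random.default_rng(0)
    noise = rng.standard_normal(cosine_series.n_samples)
    noisy = make_series(np.abs(cosine_series.counts + 5 * noise))
    clean = fit_cosinor(cosine_series, 1440.0)
    obs = fit_cosinor(noisy, 1440.0)
    assert obs.M == pytest.approx(clean.M, abs=1.0)
    assert obs.A == pytest.approx(clean.A, abs=1.0)
    assert obs.r_squared < 1.0


def _grid_oracle(t, x, T, M_range, A_range, phi_range, steps=41):
    """Brute-force SSR minimisation over an (M, A, phi) box."""
    best = (np.inf, None)
    w = 2 * np.pi / T
    for M in np.linspace(*M_range, steps):
        for A in np.linspace(*A_range, steps):
            for phi in np.linspace(*phi_range, steps):
                ssr = np.sum((x - M - A * np.cos(w * t + np.radians(phi))) ** 2)
                if ssr < best[0]:
                    best = (ssr, (M, A, phi))
    return best


def test_matches_brute_force_grid_oracle():
    """Closed-form fit agrees with an iteratively refined 3-D grid search."""
    t = np.arange(24) * 60.0
    rng = np.random.default_rng(42)
    resid = rng.normal(0, 0.5, 24).round(3)  # fixed printed residuals
    x = 10 + 5 * np.cos(2 * np.pi * t / 1440.0) + resid
    fit = fit_cosinor(make_series(x, epoch=60.0), 1440.0)
    ranges = ((5.0, 15.0), (1.0, 9.0), (-60.0, 60.0))
    for _ in range(8):  # refine the box around the incumbent optimum
        ssr, (M, A, phi) = _grid_oracle(t, x, 1440.0, *ranges)
        widths = [(hi - lo) / 8 for lo, hi in ranges]
        ranges = tuple((c - w, c + w) for c, w in zip((M, A, phi), widths))
    assert fit.M == pytest.approx(M, abs=1e-3)
    assert fit.A == pytest.approx(A, abs=1e-3)
    assert fit.phi == pytest.approx(phi, abs=1e-2)


def test_beats_random_candidates(fast_subject):
    """Closed form attains SSR <= 1000 random (M, A, phi) candidates."""
    t, x = fast_subject.times(), fast_subject.counts
    fit = fit_cosinor(fast_subject, 1440.0)
    w = 2 * np.pi / 1440.0
    ssr_fit = np.sum((x - fit.M - fit.A * np.cos(w * t + np.radians(fit.phi))) ** 2)
    rng = np.random.default_rng(1)
    for _ in range(1000):
        M = rng.uniform(0, 500)
        A = rng.uniform(0, 400)
        phi = rng.uniform(-180, 180)
        ssr = np.sum((x - M - A * np.cos(w * t + np.radians(phi))) ** 2)
        assert ssr_fit <= ssr + 1e-9


def _argmax_amplitude(t, x, grid):
    """Independent direct evaluation of the fitted amplitude over the grid."""
    amps = []
    for T in grid:
        w = 2 * np.pi / T
        D = np.column_stack([np.ones_like(t), np.cos(w * t), np.sin(w * t)])
        c, *_ = np.linalg.lstsq(D, x, rcond=None)
        amps.append(np.hypot(c[1], c[2]))
    return grid[int(np.argmax(amps))]


def test_scan_recovers_true_period():
    """Amplitude scan lands near the true period (a few minutes of
    finite-record leakage bias); the SSR criterion is exact."""
    t = np.arange(7 * 1440.0)
    x = 100 + 50 * np.cos(2 * np.pi * t / 1435.0)
    grid = np.arange(1320.0, 1561.0)
    T_star, fit = scan_period(make_series(x), grid)
    assert T_star == _argmax_amplitude(t, x, grid)
    assert abs(T_star - 1435.0) <= 5.0
    T_ssr, fit_ssr = scan_period(make_series(x), grid, criterion="ssr")
    assert T_ssr == 1435.0
    assert fit_ssr.delta_T == -5.0


def test_scan_two_period_mixture_prefers_dominant():
    t = np.arange(7 * 1440.0)
    x = 100 + 50 * np.cos(2 * np.pi * t / 1440.0) + 10 * np.cos(2 * np.pi * t / 720.0)
    grid = default_period_grid()
    T_star, _ = scan_period(make_series(x))
    assert T_star == _argmax_amplitude(t, x, grid)
    assert abs(T_star - 1440.0) <= 10.0
    T_ssr, _ = scan_period(make_series(x), criterion="ssr")
    assert abs(T_ssr - 1440.0) <= 1.0  # harmonic leakage shifts SSR by <= 1 grid step


def test_scan_white_noise_contract():
    rng = np.random.default_rng(3)
    s = make_series(np.abs(rng.standard_normal(7 * 1440)))
    T_star, fit = scan_period(s)
    assert 1320 <= T_star <= 1560
    assert abs(fit.r_squared) < 0.05


def test_scan_empty_grid_rejected(cosine_series):
    with pytest.raises(ValueError):
        scan_period(cosine_series, [])


@pytest.mark.parametrize(
    "deg,hhmm", [(232.0, "15:28"), (253.0, "16:52"), (0.0, "00:00"), (360.0, "00:00")]
)
def test_acrophase_clock(deg, hhmm):
    assert acrophase_clock(deg) == hhmm


@pytest.mark.parametrize("delta_T,slope", [(3.0, 0.75), (-24.0, -6.0), (0.0, 0.0)])
def test_acrophase_trajectory_slope(cosine_series, delta_T, slope):
    fit = fit_cosinor(cosine_series, 1440.0 + delta_T)
    traj = acrophase_trajectory(fit, 7)
    slopes = np.diff(traj)
    assert np.allclose(slopes, slope)


def test_r_squared_affine_invariant(fast_subject):
    f1 = fit_cosinor(fast_subject, 1440.0)
    scaled = make_series(3.5 * fast_subject.counts + 40.0, epoch=5.0)
    f2 = fit_cosinor(scaled, 1440.0)
    assert f2.r_squared == pytest.approx(f1.r_squared, abs=1e-12)


@pytest.mark.parametrize("start", [0.0, 123.0, 930.0])
def test_acrophase_independent_of_recording_start(start):
    """Phase-shift equivariance: clock acrophase ignores when recording began."""
    t = start + np.arange(5 * 1440.0)
    x = 50 + 20 * np.cos(2 * np.pi * (t - 928.0) / 1440.0)
    fit = fit_cosinor(make_series(x, start=start), 1440.0)
    assert fit.acrophase_deg == pytest.approx(232.0, abs=1e-8)


def test_constant_series_rejected():
    with pytest.raises(ValueError):
        fit_cosinor(make_series(np.full(100, 7.0)), 1440.0)


def test_sklearn_estimator_interface(cosine_series):
    reg = CosinorRegressor(period_grid=default_period_grid(1430, 1450, 5))
    t = cosine_series.times().reshape(-1, 1)
    reg.fit(t, cosine_series.counts)
    assert reg.get_params()["period"] == 1440.0
    pred = reg.predict(t)
    assert np.allclose(pred, cosine_series.counts, atol=1e-6)
    assert reg.score(t, cosine_series.counts) == pytest.approx(1.0)
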