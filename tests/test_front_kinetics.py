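import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import brentq
from scipy.special import erfc, erfcinv

import balwave as bw
from balwave.front_kinetics import FrontTrace


def erfc_profile(D=1.0, t=4.0, L=10.0, n=2001):
    x = np.linspace(0.0, L, n)
    return x, erfc(x / (2 * np.sqrt(D * t)))


# ---------------------------------------------------------------------------
# detect_front


def test_step_front_half_rise_at_the_step():
    # ramp over one sample so the half level is crossed exactly at x = 5
    x = np.linspace(0, 10, 101)
    prof = np.interp(x, [0, 4.95, 5.05, 10], [1.0, 1.0, 0.0, 0.0])
    assert bw.detect_front(prof, x, "half_rise") == pytest.approx(5.0, abs=1e-9)


def test_peak_convention_finds_gaussian_bump_on_plateau():
    x = np.linspace(0, 10, 501)
    prof = 1.0 * (x < 4) + 2.0 * np.exp(-((x - 3.0) ** 2) / (2 * 0.3**2))
    assert bw.detect_front(prof, x, "peak") == pytest.approx(3.0, abs=x[1] - x[0])


def test_erfc_half_rise_matches_analytic_inverse():
    x, prof = erfc_profile(D=1.0, t=4.0)
    expected = 2 * np.sqrt(4.0) * erfcinv(0.5)  # ~1.9077 um
    assert bw.detect_front(prof, x, "half_rise") == pytest.approx(expected, abs=2e-3)


def test_flat_profile_returns_no_front_sentinel():
    x = np.linspace(0, 10, 50)
    assert np.isnan(bw.detect_front(np.ones_like(x), x))
    assert np.isnan(bw.detect_front(np.ones_like(x) + 1e-4, x, noise_floor=1e-3))


def test_peak_ties_break_toward_larger_coordinate():
    x = np.arange(7.0)
    prof = np.array([0.0, 1.0, 0.5, 0.5, 1.0, 0.2, 0.0])
    assert bw.detect_front(prof, x, "peak") == 4.0


@given(a=st.floats(0.1, 100.0), b=st.floats(-5.0, 5.0))
def test_detect_front_is_affine_invariant(a, b):
    x, prof = erfc_profile(n=401)
    x0 = bw.detect_front(prof, x, "half_rise")
    x1 = bw.detect_front(a * prof + b, x, "half_rise")
    assert x1 == pytest.approx(x0, abs=1e-9)


# ---------------------------------------------------------------------------
# front_width


def test_gaussian_peak_fwhm():
    x = np.linspace(-10, 10, 2001)
    prof = 3.0 * np.exp(-(x**2) / (2 * 2.0**2))
    assert bw.front_width(prof, x, "peak") == pytest.approx(2.3548 * 2.0, rel=1e-3)


def test_ideal_step_width_collapses_to_grid_resolution():
    x = np.linspace(0, 10, 201)
    dx = x[1] - x[0]
    prof = np.where(x < 5, 1.0, 0.0)
    assert bw.front_width(prof, x, "half_rise") <= 2 * dx


def test_erfc_width_matches_brute_force_crossings():
    D, t = 1.0, 4.0
    x, prof = erfc_profile(D, t, L=15.0, n=4001)
    f = lambda z, level: erfc(z / (2 * np.sqrt(D * t))) - level
    x16 = brentq(f, 0, 15, args=(0.16,))
    x84 = brentq(f, 0, 15, args=(0.84,))
    assert bw.front_width(prof, x, "half_rise") == pytest.approx(x16 - x84, rel=1e-3)
    # scales as sqrt(4 D t)
    assert x16 - x84 == pytest.approx(
        2 * np.sqrt(D * t) * (erfcinv(0.16) - erfcinv(0.84)), rel=1e-9
    )


def test_front_width_requires_a_front():
    x = np.linspace(0, 10, 50)
    with pytest.raises(bw.NoFrontError):
        bw.front_width(np.ones_like(x), x)


# ---------------------------------------------------------------------------
# peak_ratio


def test_peak_ratio_examples():
    x = np.linspace(0, 10, 501)
    flat = np.ones_like(x)
    assert bw.peak_ratio(flat, x) == pytest.approx(1.0)
    x2 = np.linspace(0, 20, 2001)
    prof = 1.0 * (x2 <= 16) + 1.5 * np.exp(-((x2 - 16.0) ** 2) / (2 * 0.1**2))
    assert bw.peak_ratio(prof, x2) == pytest.approx(2.5, rel=1e-2)


def test_peak_ratio_needs_a_plateau_behind_the_front():
    x = np.linspace(0, 10, 501)
    prof = np.exp(-((x - 0.2) ** 2) / (2 * 0.1**2))  # peak at the boundary
    with pytest.raises(bw.NoPlateauError):
        bw.peak_ratio(prof, x)


# ---------------------------------------------------------------------------
# front_trace


def test_front_trace_on_synthetic_traveling_wave():
    kym, gt = bw.gen_ballistic_kymograph(v=0.05, W=1.0, peak_ratio=2.5, t_end=400.0)
    tr = bw.front_trace(kym, convention="peak")
    assert tr.v == pytest.approx(0.05, rel=1e-2)
    assert tr.alpha == pytest.approx(1.0, abs=0.01)
    W = tr.W[np.isfinite(tr.W)]
    assert np.std(W) < 0.15 * np.mean(W)  # self-similar: ~constant width


def test_front_trace_on_erfc_family_recovers_sqrt_scaling():
    # domain large enough that the profile decays to ~0 at all fitted times
    kym, gt = bw.gen_fickian_kymograph(D=1.0, L=40.0, n_x=400, t_end=100.0)
    tr = bw.front_trace(kym, convention="half_rise")
    assert tr.alpha == pytest.approx(0.5, abs=0.02)


def test_all_flat_kymograph_raises_insufficient_data():
    kym = bw.Kymograph(
        intensity=np.ones((10, 50)),
        positions=np.linspace(0, 10, 50),
        times=np.arange(1.0, 11.0),
    )
    with pytest.raises(bw.InsufficientDataError):
        bw.front_trace(kym)


# ---------------------------------------------------------------------------
# fits


def make_trace(t, X):
    return FrontTrace(
        t=t, X_front=X, W=np.full_like(t, np.nan), I_p_over_I0=np.full_like(t, np.nan)
    )


def test_scaling_exponent_exact_on_power_laws():
    t = np.linspace(1, 100, 60)
    assert bw.fit_scaling_exponent(make_trace(t, 3 * t), (0, 100)) == pytest.approx(
        1.0, abs=1e-10
    )
    assert bw.fit_scaling_exponent(make_trace(t, 2 * np.sqrt(t)), (0, 100)) == (
        pytest.approx(0.5, abs=1e-10)
    )


def test_scaling_exponent_under_multiplicative_noise(rng):
    t = np.linspace(1, 100, 50)
    X = 0.7 * t**0.75 * (1 + 0.01 * rng.standard_normal(50))
    assert bw.fit_scaling_exponent(make_trace(t, X), (0, 100)) == pytest.approx(
        0.75, abs=0.03
    )


def test_scaling_exponent_needs_positive_points():
    t = np.linspace(0, 10, 10)
    with pytest.raises(bw.InsufficientDataError):
        bw.fit_scaling_exponent(make_trace(t, np.zeros_like(t)), (0, 10))


def test_velocity_fits():
    t = np.linspace(0, 100, 40)
    v, se = bw.fit_velocity(make_trace(t, 0.05 * t), (0, 100))
    assert v == pytest.approx(0.05, abs=1e-12) and se == pytest.approx(0.0, abs=1e-12)
    v, se = bw.fit_velocity(make_trace(t, np.full_like(t, 3.0)), (0, 100))
    assert v == pytest.approx(0.0, abs=1e-12)


def test_velocity_fit_under_noise_is_within_three_standard_errors(rng):
    t = np.linspace(0, 100, 40)
    X = 0.05 * t + 0.02 * 5.0 * rng.standard_normal(40)
    v, se = bw.fit_velocity(make_trace(t, X), (0, 100))
    assert abs(v - 0.05) < 3 * se


def test_scaling_law_fit_examples():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    exp, pre, r2 = bw.scaling_law_fit(x, x**2)
    assert exp == pytest.approx(2.0, abs=1e-12) and r2 == pytest.approx(1.0)
    exp, pre, r2 = bw.scaling_law_fit(x, 3.0 * np.sqrt(x))
    assert exp == pytest.approx(0.5, abs=1e-12)
    assert pre == pytest.approx(3.0, rel=1e-12)
    with pytest.raises(bw.ParameterError):
        bw.scaling_law_fit([1.0, -2.0, 3.0], [1.0, 2.0, 3.0])


# ---------------------------------------------------------------------------
# classification


@pytest.mark.parametrize(
    "alpha,ratio,expected",
    [
        (0.5, 1.0, "fickian"),
        (1.0, 2.0, "ballistic_wave"),
        (1.0, 1.05, "ballistic_front"),
    ],
)
def test_classify_regime_thresholds(alpha, ratio, expected):
    t = np.linspace(1, 10, 10)
    tr = make_trace(t, t)
    tr.alpha = alpha
    tr.I_p_over_I0 = np.full_like(t, ratio)
    assert bw.classify_regime(tr) == expected


def test_classify_requires_fitted_alpha():
    t = np.linspace(1, 10, 10)
    tr = make_trace(t, t)
    with pytest.raises(bw.ParameterError):
        bw.classify_regime(tr)
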