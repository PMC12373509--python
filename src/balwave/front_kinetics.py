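"""Front tracking and transport-regime classification on kymographs.

Extracts the front position, width, velocity, peak ratio and the
displacement scaling exponent from space-time intensity maps, and labels
the transport regime:

* ``fickian`` — blurry front, displacement ~ t^0.5;
* ``ballistic_front`` — sharp front, displacement ~ t, no intensity peak;
* ``ballistic_wave`` — sharp linear front carrying a high-intensity
  invader peak (I_p/I_0 well above 1).

Kymographs in this package put the invasion origin at the low-coordinate
end, so fronts move toward larger coordinates; "behind the front" means
toward the origin.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from .errors import (
    InsufficientDataError,
    NoFrontError,
    NoPlateauError,
    ParameterError,
)
from .kymograph import Kymograph

__all__ = [
    "FrontTrace",
    "detect_front",
    "front_width",
    "peak_ratio",
    "front_trace",
    "fit_scaling_exponent",
    "fit_velocity",
    "scaling_law_fit",
    "classify_regime",
]

REGIMES = ("fickian", "ballistic_front", "ballistic_wave")


@dataclasses.dataclass
class FrontTrace:
    """Per-frame front descriptors plus the fitted kinetics.

    ``X_front`` is the displacement from the kymograph origin (um); ``W``
    the front width; ``I_p_over_I0`` the peak-to-plateau intensity ratio.
    Frames without a detectable front carry NaN.  ``v`` (um/s) and
    ``alpha`` (dimensionless) come from linear and log-log fits of
    ``X_front`` vs ``t`` inside ``fit_window``.
    """

    t: np.ndarray
    X_front: np.ndarray
    W: np.ndarray
    I_p_over_I0: np.ndarray
    v: float = np.nan
    v_stderr: float = np.nan
    alpha: float = np.nan
    regime: str | None = None
    fit_window: tuple[float, float] = (0.0, np.inf)

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.X_front)


# ---------------------------------------------------------------------------
# single-profile operations


def _check_profile(profile, positions):
    profile = np.asarray(profile, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if profile.ndim != 1 or len(profile) < 5:
        raise ParameterError("profile must be 1D with length >= 5")
    if positions.shape != profile.shape:
        raise ParameterError("positions and profile lengths differ")
    if np.any(np.diff(positions) <= 0):
        raise ParameterError("positions must be strictly increasing")
    return profile, positions


def _outermost_crossing(profile, positions, level):
    """Largest coordinate where the profile crosses ``level``, linearly
    interpolated; NaN if the profile never crosses it."""
    above = profile >= level
    # crossing between j and j+1 whenever the 'above' state changes
    changes = np.nonzero(above[:-1] != above[1:])[0]
    if len(changes) == 0:
        return np.nan
    j = changes[-1]
    p0, p1 = profile[j], profile[j + 1]
    x0, x1 = positions[j], positions[j + 1]
    return x0 + (level - p0) / (p1 - p0) * (x1 - x0)


def _nearest_crossing(profile, positions, idx, level, step):
    """First crossing of ``level`` walking from ``idx`` in ``step``
    direction; falls back to the domain edge if the flank never drops."""
    j = idx
    while 0 <= j + step < len(profile):
        if profile[j + step] < level:
            p0, p1 = profile[j], profile[j + step]
            x0, x1 = positions[j], positions[j + step]
            return x0 + (level - p0) / (p1 - p0) * (x1 - x0)
        j += step
    return positions[-1] if step > 0 else positions[0]


def detect_front(
    profile,
    positions,
    convention: str = "half_rise",
    noise_floor: float = 0.0,
) -> float:
    """Front coordinate of a single intensity profile (um).

    ``"peak"``: position of the intensity maximum (wave regime); ties are
    broken toward the larger coordinate.  ``"half_rise"``: outermost
    crossing of the mid level between the profile extremes, interpolated
    between samples.  A flat profile (max - min <= ``noise_floor``)
    returns NaN, the no-front sentinel.
    """
    profile, positions = _check_profile(profile, positions)
    lo, hi = float(np.min(profile)), float(np.max(profile))
    if hi - lo <= max(noise_floor, 0.0):
        return np.nan
    if convention == "peak":
        idx = len(profile) - 1 - int(np.argmax(profile[::-1]))
        return float(positions[idx])
    if convention == "half_rise":
        x = _outermost_crossing(profile, positions, 0.5 * (hi + lo))
        return float(x) if np.isfinite(x) else float(positions[-1])
    raise ParameterError(f"unknown front convention {convention!r}")


def front_width(profile, positions, convention: str = "peak") -> float:
    """Front width W (um).

    ``"peak"``: FWHM of the intensity peak (half level between the
    profile minimum and the peak).  ``"half_rise"``: distance between the
    outermost 84% and 16% crossings of the rise (the blurry-front width
    measure).  Raises :class:`NoFrontError` on a flat profile.
    """
    profile, positions = _check_profile(profile, positions)
    lo, hi = float(np.min(profile)), float(np.max(profile))
    if hi <= lo:
        raise NoFrontError("flat profile: no front to measure")
    if convention == "peak":
        idx = len(profile) - 1 - int(np.argmax(profile[::-1]))
        # FWHM of the peak relative to its local background: the lowest
        # intensity behind the peak (the invaded plateau in the wave
        # regime, ~zero for an isolated bump).
        base = float(np.min(profile[: idx + 1])) if idx > 0 else lo
        level = base + 0.5 * (profile[idx] - base)
        right = _nearest_crossing(profile, positions, idx, level, step=+1)
        left = _nearest_crossing(profile, positions, idx, level, step=-1)
        return float(right - left)
    if convention == "half_rise":
        x84 = _outermost_crossing(profile, positions, lo + 0.84 * (hi - lo))
        x16 = _outermost_crossing(profile, positions, lo + 0.16 * (hi - lo))
        if not (np.isfinite(x84) and np.isfinite(x16)):
            raise NoFrontError("could not locate the 16%/84% rise levels")
        return float(abs(x16 - x84))
    raise ParameterError(f"unknown width convention {convention!r}")


def peak_ratio(profile, positions=None, band_fraction: float = 0.1) -> float:
    """Peak intensity I_p over the plateau intensity I_0 behind the front.

    The plateau is the median over the ``band_fraction`` of the position
    span immediately behind (origin side of) the peak, which is robust to
    the peak itself.  Raises :class:`NoPlateauError` when the peak sits
    too close to the origin for a plateau band to exist.
    """
    profile = np.asarray(profile, dtype=float)
    if positions is None:
        positions = np.arange(len(profile), dtype=float)
    profile, positions = _check_profile(profile, positions)
    idx = len(profile) - 1 - int(np.argmax(profile[::-1]))
    span = positions[-1] - positions[0]
    band_lo = positions[idx] - band_fraction * span
    if band_lo < positions[0]:
        raise NoPlateauError("front too close to the boundary: no plateau behind it")
    in_band = (positions >= band_lo) & (positions < positions[idx])
    if np.count_nonzero(in_band) < 3:
        raise NoPlateauError("plateau band contains fewer than 3 samples")
    plateau = float(np.median(profile[in_band]))
    if plateau <= 0:
        raise NoPlateauError("non-positive plateau intensity behind the front")
    return float(profile[idx] / plateau)


# ---------------------------------------------------------------------------
# per-kymograph operations


def front_trace(
    kym: Kymograph,
    convention: str = "half_rise",
    width_convention: str | None = None,
    fit_window: tuple[float, float] | None = None,
    noise_floor: float = 0.0,
) -> FrontTrace:
    """Track the front through all frames and fit its kinetics.

    Per frame: :func:`detect_front`, :func:`front_width` and
    :func:`peak_ratio` (NaN where undefined).  Frames flagged no-front
    are excluded; fewer than 3 valid frames raise
    :class:`InsufficientDataError`.  The default fit window excludes the
    final 20% of frames, where fronts from opposite sides of a real
    condensate interfere and accelerate.
    """
    if kym.n_times < 5:
        raise InsufficientDataError("front_trace needs at least 5 frames")
    if width_convention is None:
        width_convention = convention
    n = kym.n_times
    X = np.full(n, np.nan)
    W = np.full(n, np.nan)
    R = np.full(n, np.nan)
    for i in range(n):
        pos, prof = kym.profile(i)
        x_f = detect_front(prof, pos, convention=convention, noise_floor=noise_floor)
        if not np.isfinite(x_f):
            continue
        X[i] = abs(x_f - kym.origin)
        try:
            W[i] = front_width(prof, pos, convention=width_convention)
        except NoFrontError:
            pass
        try:
            R[i] = peak_ratio(prof, pos)
        except NoPlateauError:
            pass
    valid = np.isfinite(X)
    if np.count_nonzero(valid) < 3:
        raise InsufficientDataError(
            f"only {np.count_nonzero(valid)} frames carry a detectable front"
        )
    if fit_window is None:
        fit_window = (0.0, 0.8 * float(kym.times[-1]))
    trace = FrontTrace(
        t=kym.times.copy(), X_front=X, W=W, I_p_over_I0=R, fit_window=fit_window
    )
    try:
        trace.alpha = fit_scaling_exponent(trace, fit_window)
    except InsufficientDataError:
        pass
    try:
        trace.v, trace.v_stderr = fit_velocity(trace, fit_window)
    except InsufficientDataError:
        pass
    return trace


def _window_points(trace, window, positive: bool):
    if isinstance(trace, FrontTrace):
        t, X = trace.t, trace.X_front
    else:
        t, X = trace
        t = np.asarray(t, dtype=float)
        X = np.asarray(X, dtype=float)
    lo, hi = window
    keep = np.isfinite(X) & (t >= lo) & (t <= hi)
    if positive:
        keep &= (t > 0) & (X > 0)
    return t[keep], X[keep]


def fit_scaling_exponent(trace, window: tuple[float, float] | None = None) -> float:
    """Displacement exponent alpha from the slope of log X vs log t.

    ``trace`` may be a :class:`FrontTrace` or a ``(times, X)`` pair.  The
    window defaults to excluding the final 20% of the trace (end-stage
    interference).  alpha = 1 marks ballistic, alpha = 0.5 Fickian
    transport.
    """
    if window is None:
        t_all = trace.t if isinstance(trace, FrontTrace) else np.asarray(trace[0])
        window = (0.0, 0.8 * float(t_all[-1]))
    t, X = _window_points(trace, window, positive=True)
    if len(t) < 5:
        raise InsufficientDataError(
            f"scaling fit needs >= 5 positive points in window, got {len(t)}"
        )
    slope, _ = np.polyfit(np.log(t), np.log(X), 1)
    return float(slope)


def fit_velocity(trace, window: tuple[float, float] | None = None):
    """Front velocity from linear least squares of X vs t in the window.

    Returns ``(v, standard error)`` in um/s.
    """
    if window is None:
        t_all = trace.t if isinstance(trace, FrontTrace) else np.asarray(trace[0])
        window = (0.0, 0.8 * float(t_all[-1]))
    t, X = _window_points(trace, window, positive=False)
    if len(t) < 3:
        raise InsufficientDataError(f"velocity fit needs >= 3 points, got {len(t)}")
    res = stats.linregress(t, X)
    return float(res.slope), float(res.stderr)


def scaling_law_fit(xs, ys):
    """Power-law fit ``y = c * x**p`` by log-log regression.

    Returns ``(exponent, prefactor, r_squared)``.  Used for the front
    velocity vs invader concentration law (exponent ~0.5) and the
    velocity vs front width correlation (exponent ~1).
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if len(xs) != len(ys) or len(xs) < 3:
        raise ParameterError("scaling_law_fit needs >= 3 (x, y) pairs")
    if np.any(xs <= 0) or np.any(ys <= 0):
        raise ParameterError("scaling_law_fit requires strictly positive inputs")
    res = stats.linregress(np.log(xs), np.log(ys))
    return float(res.slope), float(np.exp(res.intercept)), float(res.rvalue**2)


def classify_regime(
    trace: FrontTrace,
    alpha_fickian: float = 0.7,
    wave_ratio: float = 1.2,
) -> str:
    """Label the transport regime of a fitted trace.

    ``fickian`` if the displacement exponent is below ``alpha_fickian``;
    otherwise ``ballistic_wave`` when the median peak ratio reaches
    ``wave_ratio``, else ``ballistic_front``.  Thresholds are
    configurable; the defaults separate the three canonical parameter
    regimes cleanly (0.5 vs ~1 exponents, peak ratios ~1 vs >~2).
    """
    if not np.isfinite(trace.alpha):
        raise ParameterError("classify_regime requires a trace with a fitted alpha")
    if trace.alpha < alpha_fickian:
        return "fickian"
    ratios = trace.I_p_over_I0[np.isfinite(trace.I_p_over_I0)]
    median_ratio = float(np.median(ratios)) if len(ratios) else 1.0
    if median_ratio >= wave_ratio:
        return "ballistic_wave"
    return "ballistic_front"
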