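"""FRAP quantification and point-bleach diffusivity estimation.

Two estimators used to characterise condensate interior dynamics:

* ROI bleaching with double normalization,
  ``I_norm(t) = [I_ROI(t)/I_ROI(t0)] * [I_ref(t0)/I_ref(t)]``,
  which cancels acquisition photobleaching, followed by the
  half-recovery time ``t_1/2``.  Arrested condensates show no recovery
  within the observation horizon (6000 s by convention), and
  ``1/6000 s^-1`` is then reported as ``1/t_1/2``.
* Point bleaching: the bleached spot relaxes as a Gaussian whose
  variance grows linearly, ``sigma^2(t) = sigma0^2 + 2 D t``, so the
  diffusion coefficient is half the slope of ``sigma^2`` vs ``t``.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import optimize, stats

from .errors import FitError, InsufficientDataError, ParameterError

__all__ = [
    "FrapRecord",
    "PointBleachSeries",
    "double_normalize",
    "half_recovery_time",
    "gaussian_sigma2",
    "fit_diffusion_coefficient",
    "ARRESTED_T_HALF",
]

#: Observation horizon assigned to arrested condensates (s).
ARRESTED_T_HALF = 6000.0


@dataclasses.dataclass
class FrapRecord:
    """A FRAP intensity time series (bleached ROI plus reference region).

    ``t0_index`` marks the first pre-bleach frame, whose intensities are
    the normalization references.  ``T_max`` is the horizon beyond which
    a non-recovering condensate is declared arrested.
    """

    times: np.ndarray
    I_ROI: np.ndarray
    I_ref: np.ndarray
    t0_index: int = 0
    T_max: float = ARRESTED_T_HALF

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.I_ROI = np.asarray(self.I_ROI, dtype=float)
        self.I_ref = np.asarray(self.I_ref, dtype=float)
        if not (len(self.times) == len(self.I_ROI) == len(self.I_ref)):
            raise ParameterError("times, I_ROI and I_ref must have equal length")
        if not (0 <= self.t0_index < len(self.times)):
            raise ParameterError("t0_index out of range")


@dataclasses.dataclass
class PointBleachSeries:
    """Per-frame 1D intensity profiles of a spreading point bleach."""

    times: np.ndarray
    positions: np.ndarray
    profiles: np.ndarray  # (n_frames, n_positions)
    sigma2: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.profiles = np.asarray(self.profiles, dtype=float)
        if self.profiles.shape != (len(self.times), len(self.positions)):
            raise ParameterError("profiles shape must be (n_frames, n_positions)")

    def compute_sigma2(self) -> np.ndarray:
        """Fit every frame with a Gaussian and cache the variances."""
        self.sigma2 = np.array(
            [gaussian_sigma2(p, self.positions) for p in self.profiles]
        )
        return self.sigma2


def double_normalize(rec: FrapRecord) -> np.ndarray:
    """Doubly normalized recovery curve of the bleached region.

    ``I_norm(t) = [I_ROI(t) / I_ROI(t0)] * [I_ref(t0) / I_ref(t)]``; the
    reference-region factor removes global acquisition bleaching, so the
    curve is invariant under any common multiplicative drift of both
    channels and equals 1 at the pre-bleach frame by construction.
    """
    i0 = rec.t0_index
    if rec.I_ROI[i0] <= 0:
        raise ParameterError("pre-bleach ROI intensity must be positive")
    if np.any(rec.I_ref <= 0):
        raise ParameterError("reference intensity must be positive at all frames")
    return (rec.I_ROI / rec.I_ROI[i0]) * (rec.I_ref[i0] / rec.I_ref)


def half_recovery_time(
    times,
    curve,
    T_max: float = ARRESTED_T_HALF,
    recovery_threshold: float = 0.05,
) -> tuple[float, bool]:
    """Half-recovery time of a normalized FRAP curve.

    The recovery midpoint is ``(floor + plateau)/2`` with the floor
    taken at the post-bleach minimum and the plateau as the median of
    the final 10% of frames, so an immobile fraction does not distort
    ``t_1/2``.  The first crossing wins; crossings are linearly
    interpolated between frames.  If the curve recovers by less than
    ``recovery_threshold`` (relative) or never reaches the midpoint
    within ``T_max``, the record is arrested: returns ``(T_max, True)``.
    """
    times = np.asarray(times, dtype=float)
    curve = np.asarray(curve, dtype=float)
    if len(times) != len(curve) or len(times) < 3:
        raise ParameterError("need matching times/curve with >= 3 frames")
    i_floor = int(np.argmin(curve))
    if i_floor == len(curve) - 1:
        raise InsufficientDataError("no post-bleach frames after the minimum")
    floor = float(curve[i_floor])
    n_tail = max(1, len(curve) // 10)
    plateau = float(np.median(curve[-n_tail:]))
    scale = max(abs(floor), abs(plateau), 1e-300)
    if plateau - floor <= recovery_threshold * scale:
        return float(T_max), True
    target = 0.5 * (floor + plateau)
    post = curve[i_floor:]
    above = post >= target
    idx = np.nonzero(above)[0]
    # ignore the floor frame itself; look for the first later crossing
    idx = idx[idx > 0]
    if len(idx) == 0:
        return float(T_max), True
    j = int(idx[0]) + i_floor
    t_prev, t_next = times[j - 1], times[j]
    c_prev, c_next = curve[j - 1], curve[j]
    if c_next == c_prev:
        t_cross = t_next
    else:
        t_cross = t_prev + (target - c_prev) / (c_next - c_prev) * (t_next - t_prev)
    t_half = float(t_cross - times[i_floor])
    if t_half > T_max:
        return float(T_max), True
    return t_half, False


def gaussian_sigma2(profile, positions, min_amplitude: float | None = None) -> float:
    """Squared Gaussian width of a bleach dip (or peak) profile, um^2.

    Fits ``A * exp(-(x - mu)^2 / (2 sigma^2)) + c`` by nonlinear least
    squares (the sign of ``A`` is free, so dips and peaks both work) and
    returns ``sigma^2``.
    """
    profile = np.asarray(profile, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if len(profile) != len(positions) or len(profile) < 5:
        raise ParameterError("need matching profile/positions with >= 5 samples")
    span = positions[-1] - positions[0]
    c0 = float(np.median(profile))
    idx = int(np.argmax(np.abs(profile - c0)))
    A0 = float(profile[idx] - c0)
    amp_floor = min_amplitude if min_amplitude is not None else 1e-9 * (abs(c0) + 1.0)
    if abs(A0) <= amp_floor:
        raise FitError("profile amplitude below the noise floor: nothing to fit")

    def model(x, A, mu, sigma, c):
        return A * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2)) + c

    p0 = (A0, float(positions[idx]), span / 10.0, c0)
    try:
        popt, _ = optimize.curve_fit(model, positions, profile, p0=p0, maxfev=10000)
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        raise FitError(f"Gaussian fit did not converge: {exc}") from exc
    sigma2 = float(popt[2] ** 2)
    resid = float(np.sqrt(np.mean((model(positions, *popt) - profile) ** 2)))
    if not np.isfinite(sigma2) or sigma2 <= 0 or sigma2 > (10.0 * span) ** 2:
        raise FitError(f"unphysical Gaussian width (sigma^2={sigma2:g}, rms={resid:g})")
    return sigma2


def fit_diffusion_coefficient(series: PointBleachSeries) -> tuple[float, float]:
    """Diffusion coefficient from the Gaussian-spreading law.

    Least-squares slope ``m`` of ``sigma^2`` vs ``t`` gives
    ``D = m / 2`` (um^2/s); returns ``(D, standard error)``.
    """
    if series.sigma2 is None:
        series.compute_sigma2()
    sigma2 = np.asarray(series.sigma2, dtype=float)
    keep = np.isfinite(sigma2)
    if np.count_nonzero(keep) < 3:
        raise InsufficientDataError("need >= 3 frames with a valid sigma^2")
    res = stats.linregress(series.times[keep], sigma2[keep])
    return float(res.slope / 2.0), float(res.stderr / 2.0)
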