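"""Synthetic microscopy data with known ground truth.

Every analysis stage in this package has a matching generator here, so
the whole pipeline can be validated as closed loops (generate with a
known parameter, analyse, recover it) without any experimental
recordings:

* constant-source Fickian invasion kymographs (erfc profiles);
* traveling sharp-front kymographs with a high-intensity peak;
* exponential FRAP recovery with immobile fractions and global
  acquisition bleaching;
* point-bleach stacks with Gaussian spreading
  ``sigma^2 = sigma0^2 + 2 D t``;
* mono/multi-exponential photon decays with Poisson (multinomial)
  counting noise.

Noise models are multiplicative Gaussian (camera/CLSM recordings,
``noise`` = relative s.d.) and photon-counting noise (decays).  All
stochastic outputs are driven by an explicit seed and regenerate
bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
from scipy.special import erfc

from .errors import ParameterError
from .frap import FrapRecord, PointBleachSeries
from .kymograph import Kymograph
from .phasor import DecayHistogram

__all__ = [
    "GroundTruth",
    "write_ground_truth",
    "gen_fickian_kymograph",
    "gen_ballistic_kymograph",
    "gen_frap_series",
    "gen_pointbleach_stack",
    "gen_decay",
    "expected_decay_histogram",
]

GAUSS_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))  # FWHM = 2.3548 * sigma


@dataclasses.dataclass
class GroundTruth:
    """Sidecar record of what a generator produced and from which truth."""

    generator: str
    params: dict
    noise: str
    seed: int | None
    warnings: list = dataclasses.field(default_factory=list)


def write_ground_truth(gt: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(dataclasses.asdict(gt), indent=1, default=float))
    return path


def _apply_mult_noise(arr: np.ndarray, noise: float, rng) -> np.ndarray:
    if noise <= 0:
        return arr
    return arr * (1.0 + noise * rng.standard_normal(arr.shape))


def _noise_tag(noise: float) -> str:
    return "none" if noise <= 0 else f"gaussian({noise:g})"


def gen_fickian_kymograph(
    D: float,
    u_res: float = 1.0,
    L: float = 30.0,
    n_x: int = 300,
    n_t: int = 120,
    t_end: float = 400.0,
    noise: float = 0.0,
    seed: int | None = None,
) -> tuple[Kymograph, GroundTruth]:
    """Constant-source Fickian invasion: ``I(x, t) = u_res erfc(x / 2 sqrt(D t))``.

    The half-rise front position grows as ``sqrt(t)`` (exponent 0.5); at
    the source ``x = 0`` the intensity stays pinned at ``u_res``.
    """
    if D <= 0:
        raise ParameterError(f"D must be > 0, got {D}")
    rng = np.random.default_rng(seed)
    times = np.linspace(t_end / n_t, t_end, n_t)
    x = np.linspace(0.0, L, n_x)
    intensity = u_res * erfc(x[None, :] / (2.0 * np.sqrt(D * times[:, None])))
    intensity = _apply_mult_noise(intensity, noise, rng)
    kym = Kymograph(intensity, x, times, origin=0.0,
                    meta={"generator": "fickian", "D": D, "u_res": u_res})
    gt = GroundTruth(
        "gen_fickian_kymograph",
        {"D": D, "u_res": u_res, "L": L, "t_end": t_end, "exponent": 0.5},
        _noise_tag(noise),
        seed,
    )
    return kym, gt


def gen_ballistic_kymograph(
    v: float,
    W: float,
    peak_ratio: float = 2.0,
    plateau: float = 1.0,
    L: float = 30.0,
    n_x: int = 400,
    n_t: int = 120,
    t_end: float = 400.0,
    noise: float = 0.0,
    seed: int | None = None,
) -> tuple[Kymograph, GroundTruth]:
    """Self-similar traveling front at ``x = v t``.

    Behind the front a plateau of the given intensity; at the front a
    Gaussian peak of height ``peak_ratio * plateau`` and FWHM ``W``;
    zero ahead.  ``peak_ratio = 1`` gives the peak-free sharp front
    (ballistic front regime); ratios well above 1 give the wave regime.
    """
    if v <= 0 or W <= 0:
        raise ParameterError("v and W must be > 0")
    if peak_ratio < 1:
        raise ParameterError(f"peak_ratio must be >= 1, got {peak_ratio}")
    rng = np.random.default_rng(seed)
    times = np.linspace(t_end / n_t, t_end, n_t)
    x = np.linspace(0.0, L, n_x)
    sigma = W / GAUSS_FWHM
    xf = v * times[:, None]
    behind = np.where(x[None, :] <= xf, plateau, 0.0)
    peak = peak_ratio * plateau * np.exp(-((x[None, :] - xf) ** 2) / (2.0 * sigma**2))
    intensity = _apply_mult_noise(np.maximum(behind, peak), noise, rng)
    gt = GroundTruth(
        "gen_ballistic_kymograph",
        {"v": v, "W": W, "peak_ratio": peak_ratio, "plateau": plateau,
         "t_end": t_end, "exponent": 1.0},
        _noise_tag(noise),
        seed,
    )
    if v * t_end > L:
        gt.warnings.append(
            f"front exits the domain at t = {L / v:.6g} s, before t_end = {t_end:g} s"
        )
    kym = Kymograph(intensity, x, times, origin=0.0,
                    meta={"generator": "ballistic", "v": v, "W": W})
    return kym, gt


def gen_frap_series(
    t_half: float,
    floor: float = 0.2,
    plateau: float = 1.0,
    T_max: float = 6000.0,
    global_bleach_rate: float = 0.0,
    n_pre: int = 5,
    n_post: int = 150,
    dt: float = 2.0,
    noise: float = 0.0,
    seed: int | None = None,
) -> tuple[FrapRecord, GroundTruth]:
    """Exponential FRAP recovery with an immobile fraction.

    Post-bleach ROI intensity ``floor + (plateau - floor) * (1 -
    exp(-t ln2 / t_half))``, with both ROI and reference channels decayed
    by ``exp(-global_bleach_rate * t)`` (acquisition bleaching that the
    double normalization must cancel).  ``t_half = inf`` encodes an
    arrested condensate that never recovers.
    """
    if not (0 <= floor < plateau):
        raise ParameterError("need 0 <= floor < plateau")
    if t_half <= 0:
        raise ParameterError("t_half must be positive (use inf for arrested)")
    rng = np.random.default_rng(seed)
    times = np.arange(n_pre + n_post, dtype=float) * dt
    t_bleach = times[n_pre]
    rel = times - t_bleach
    if math.isinf(t_half):
        recovery = np.zeros_like(times)
    else:
        recovery = 1.0 - np.exp(-np.maximum(rel, 0.0) * math.log(2.0) / t_half)
    roi = np.where(times < t_bleach, plateau, floor + (plateau - floor) * recovery)
    decay = np.exp(-global_bleach_rate * times)
    rec = FrapRecord(
        times=times,
        I_ROI=_apply_mult_noise(roi * decay, noise, rng),
        I_ref=_apply_mult_noise(plateau * decay, noise, rng),
        t0_index=0,
        T_max=T_max,
    )
    gt = GroundTruth(
        "gen_frap_series",
        {"t_half": t_half, "floor": floor, "plateau": plateau,
         "global_bleach_rate": global_bleach_rate, "arrested": math.isinf(t_half)},
        _noise_tag(noise),
        seed,
    )
    return rec, gt


def gen_pointbleach_stack(
    D: float,
    sigma0: float = 1.0,
    n_frames: int = 30,
    dt: float = 1.0,
    depth: float = 0.8,
    half_width: float | None = None,
    n_x: int = 201,
    noise: float = 0.0,
    seed: int | None = None,
) -> tuple[PointBleachSeries, GroundTruth]:
    """Point-bleach stack with Gaussian spreading.

    Per-frame dip ``1 - depth * (sigma0 / sigma(t)) * exp(-x^2 / (2
    sigma^2(t)))`` with ``sigma^2(t) = sigma0^2 + 2 D t``; the amplitude
    shrinks as the bleached 'hole' spreads, conserving its area.
    """
    if D < 0 or sigma0 <= 0:
        raise ParameterError("need D >= 0 and sigma0 > 0")
    rng = np.random.default_rng(seed)
    times = np.arange(n_frames, dtype=float) * dt
    sigma2 = sigma0**2 + 2.0 * D * times
    if half_width is None:
        half_width = 6.0 * math.sqrt(float(sigma2[-1]))
    x = np.linspace(-half_width, half_width, n_x)
    amp = depth * sigma0 / np.sqrt(sigma2)
    profiles = 1.0 - amp[:, None] * np.exp(-(x[None, :] ** 2) / (2.0 * sigma2[:, None]))
    series = PointBleachSeries(
        times=times,
        positions=x,
        profiles=_apply_mult_noise(profiles, noise, rng),
    )
    gt = GroundTruth(
        "gen_pointbleach_stack",
        {"D": D, "sigma0": sigma0, "depth": depth, "dt": dt},
        _noise_tag(noise),
        seed,
    )
    return series, gt


def _folded_bin_probabilities(tau_list, weights, T, n_bins) -> np.ndarray:
    """Exact bin probabilities of a periodically excited exponential mixture.

    Each component is the decay ``exp(-t/tau)`` wrapped into [0, T); its
    bin mass is the integral over the bin normalized by ``1 - exp(-T/tau)``.
    """
    edges = np.linspace(0.0, T, n_bins + 1)
    p = np.zeros(n_bins)
    for tau, wgt in zip(tau_list, weights):
        comp = np.exp(-edges[:-1] / tau) - np.exp(-edges[1:] / tau)
        p += wgt * comp / (1.0 - math.exp(-T / tau))
    return p / np.sum(p)


def expected_decay_histogram(
    tau_list, weights, T: float = 25.0, n_bins: int = 256, total_counts: float = 1e5
) -> DecayHistogram:
    """Noiseless expectation of :func:`gen_decay` (float counts).

    Useful as an exact oracle: phasors of these histograms obey the
    semicircle and convex-mixture identities to machine precision.
    """
    tau_list, weights = _check_mixture(tau_list, weights)
    p = _folded_bin_probabilities(tau_list, weights, T, n_bins)
    centres = (np.arange(n_bins) + 0.5) * (T / n_bins)
    return DecayHistogram(centres, total_counts * p, T)


def _check_mixture(tau_list, weights):
    tau_list = np.atleast_1d(np.asarray(tau_list, dtype=float))
    weights = np.atleast_1d(np.asarray(weights, dtype=float))
    if tau_list.shape != weights.shape:
        raise ParameterError("tau_list and weights must have equal length")
    if np.any(tau_list <= 0):
        raise ParameterError("all lifetimes must be positive")
    if abs(float(np.sum(weights)) - 1.0) > 1e-9 or np.any(weights < 0):
        raise ParameterError("weights must be non-negative and sum to 1")
    return tau_list, weights


def gen_decay(
    tau_list,
    weights,
    T: float = 25.0,
    n_bins: int = 256,
    total_counts: int = 100_000,
    seed: int | None = None,
) -> tuple[DecayHistogram, GroundTruth]:
    """Photon-decay histogram of an exponential mixture with counting noise.

    Photons are multinomially distributed over the bins of the
    periodically folded mixture density — the exact counting statistics
    of time-correlated single-photon counting at fixed total counts.
    """
    tau_list, weights = _check_mixture(tau_list, weights)
    if total_counts <= 0:
        raise ParameterError("total_counts must be positive")
    rng = np.random.default_rng(seed)
    p = _folded_bin_probabilities(tau_list, weights, T, n_bins)
    counts = rng.multinomial(int(total_counts), p)
    centres = (np.arange(n_bins) + 0.5) * (T / n_bins)
    decay = DecayHistogram(centres, counts.astype(float), T)
    gt = GroundTruth(
        "gen_decay",
        {"tau_list": tau_list.tolist(), "weights": weights.tolist(),
         "T": T, "total_counts": int(total_counts)},
        "poisson",
        seed,
    )
    return decay, gt
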