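"""Model parameters for the condensate invasion simulator.

The reaction-diffusion model describes the uptake of a short "invader"
oligonucleotide into an arrested biomolecular condensate whose interior
carries complementary barcode domains.  Free invader diffuses slowly in
arrested material (``D0``) and fast in swollen, dynamized material
(``D1``); it binds barcodes irreversibly (``k_bind``), the bound complex
converts first-order from an arrested to a swollen state (``k_swell``),
and swollen material dilates by the volumetric factor ``f_swell``.  A
volume element switches its diffusivity from ``D0`` to ``D1`` once its
swollen fraction exceeds the threshold ``theta``.

Units are micrometres, seconds and micromolar throughout, except
``m_total`` which is conventionally quoted in millimolar (the barcode
concentration inside the condensate is of order 1 mM).
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path
from typing import Iterator

import yaml

from .errors import ParameterError

GEOMETRIES = ("cartesian_1d", "radial_1d")

#: Canonical parameter presets shipped with the package (YAML files).
PRESETS = ("ballistic_wave", "ballistic_front", "fickian")


@dataclasses.dataclass
class ModelParams:
    """All rate, diffusivity and geometry constants of the invasion model.

    Attributes
    ----------
    D0, D1:
        Free-invader diffusivity in arrested / swollen regions, um^2/s.
    k_bind:
        Bimolecular invader-barcode binding rate constant, 1/(uM s).
    k_swell:
        First-order arrested-to-swollen conversion rate of the bound
        complex, 1/s.
    f_swell:
        Volumetric swelling factor of fully converted material (>= 1).
    theta:
        Swollen-fraction threshold for the D0 -> D1 switch, in (0, 1].
    m_total:
        Initial barcode concentration inside the condensate, mM.
    u_res:
        Reservoir (bath) invader concentration at the boundary, uM.
    L:
        Domain length: slab depth (cartesian) or radius (radial), um.
    n_cells:
        Number of material grid cells (>= 10).
    geometry:
        ``"cartesian_1d"`` or ``"radial_1d"``.
    t_end, dt_out:
        Total simulated time and kymograph output interval, s.
    dt_sim:
        Internal macro time step, s.  ``None`` selects ``t_end / 8000``
        (capped at ``dt_out``), which resolves the front transit time by
        a comfortable margin at the default presets.
    switch_width:
        Logistic smoothing width (in swollen fraction) of the
        diffusivity switch; 0 gives the hard step rule.
    n_x_out:
        Number of points of the fixed lab-frame output raster.
        ``None`` selects ``4 * n_cells``.
    """

    D0: float
    D1: float
    k_bind: float
    k_swell: float
    f_swell: float
    theta: float
    m_total: float
    u_res: float
    L: float
    n_cells: int
    geometry: str = "cartesian_1d"
    t_end: float = 1.0e6
    dt_out: float = 5.0e3
    dt_sim: float | None = None
    switch_width: float = 0.0
    n_x_out: int | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (self.D0 > 0):
            raise ParameterError(f"D0 must be > 0, got {self.D0}")
        if not (self.D1 >= self.D0):
            raise ParameterError(f"D1 must be >= D0, got D1={self.D1}, D0={self.D0}")
        if self.k_bind < 0:
            raise ParameterError(f"k_bind must be >= 0, got {self.k_bind}")
        if self.k_swell < 0:
            raise ParameterError(f"k_swell must be >= 0, got {self.k_swell}")
        if self.f_swell < 1:
            raise ParameterError(f"f_swell must be >= 1, got {self.f_swell}")
        if not (0 < self.theta <= 1):
            raise ParameterError(f"theta must be in (0, 1], got {self.theta}")
        if not (self.m_total > 0):
            raise ParameterError(f"m_total must be > 0, got {self.m_total}")
        if self.u_res < 0:
            raise ParameterError(f"u_res must be >= 0, got {self.u_res}")
        if not (self.L > 0):
            raise ParameterError(f"L must be > 0, got {self.L}")
        if self.n_cells < 10:
            raise ParameterError(f"n_cells must be >= 10, got {self.n_cells}")
        if self.geometry not in GEOMETRIES:
            raise ParameterError(
                f"geometry must be one of {GEOMETRIES}, got {self.geometry!r}"
            )
        if not (self.t_end > 0 and self.dt_out > 0):
            raise ParameterError("t_end and dt_out must be > 0")
        if self.dt_sim is not None and not (self.dt_sim > 0):
            raise ParameterError("dt_sim must be > 0 or None")
        if self.switch_width < 0:
            raise ParameterError("switch_width must be >= 0")

    # -- derived quantities -------------------------------------------------

    @property
    def m_total_uM(self) -> float:
        """Initial barcode concentration in uM (m_total is quoted in mM)."""
        return 1.0e3 * self.m_total

    @property
    def g_f(self) -> float:
        """Linear expansion factor of a fully swollen cell width.

        In the 1D-volumetric (cartesian) interpretation a 1D volume *is*
        a length, so ``g_f = f_swell`` and full swelling dilutes the
        conserved barcode fourfold at the default ``f_swell = 4``.  In
        radial geometry the volumetric factor acts on r^3, so radial
        widths expand by ``f_swell**(1/3)``.
        """
        if self.geometry == "cartesian_1d":
            return self.f_swell
        return self.f_swell ** (1.0 / 3.0)

    @property
    def dx(self) -> float:
        """Initial (unswollen) material cell width, um."""
        return self.L / self.n_cells

    def resolved_dt_sim(self) -> float:
        if self.dt_sim is not None:
            return self.dt_sim
        return min(self.dt_out, self.t_end / 8000.0)

    def resolved_n_x_out(self) -> int:
        return self.n_x_out if self.n_x_out is not None else 4 * self.n_cells

    def replace(self, **changes) -> "ModelParams":
        """Return a validated copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    # -- config I/O ---------------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelParams":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def load_preset(name: str, **overrides) -> ModelParams:
    """Load one of the canonical parameter presets shipped as YAML config.

    ``"ballistic_wave"``, ``"ballistic_front"`` and ``"fickian"`` are the
    three canonical transport regimes: a sharp linear-in-time front with a
    high-intensity invader peak, the same sharp linear front without the
    peak (fast swelling), and classical blurry sqrt-of-time invasion
    (no diffusivity contrast).
    """
    if name not in PRESETS:
        raise ParameterError(f"unknown preset {name!r}; available: {PRESETS}")
    text = resources.files("balwave").joinpath(f"presets/{name}.yaml").read_text()
    d = yaml.safe_load(text)
    d.update(overrides)
    return ModelParams.from_dict(d)


def iter_presets() -> Iterator[tuple[str, ModelParams]]:
    for name in PRESETS:
        yield name, load_preset(name)
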