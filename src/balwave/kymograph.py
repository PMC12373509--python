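"""Space-time intensity maps (kymographs) and their text/TIFF serialization.

A kymograph is the common currency between the invasion simulator, the
synthetic-data generators and the front-kinetics analysis: a matrix of
intensities with one row per time point and one column per position along
the line through the condensate.  The position axis always increases away
from the invasion origin (``origin``, usually the reservoir boundary at
coordinate 0), so fronts propagate toward larger coordinates.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .errors import ParameterError


@dataclasses.dataclass
class Kymograph:
    """Space-time intensity matrix with coordinates.

    ``intensity[i, j]`` is the signal at time ``times[i]`` and position
    ``positions[j]``.  Small negative intensities (e.g. from noise after
    background subtraction) are clamped to zero at construction.
    """

    intensity: np.ndarray  # (n_times, n_positions), arbitrary units >= 0
    positions: np.ndarray  # um, strictly increasing
    times: np.ndarray      # s, strictly increasing
    origin: float = 0.0    # coordinate of the invasion origin
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.intensity.ndim != 2:
            raise ParameterError("intensity must be a 2D array (n_times, n_positions)")
        nt, nx = self.intensity.shape
        if self.positions.shape != (nx,):
            raise ParameterError(
                f"positions length {self.positions.shape} does not match intensity columns {nx}"
            )
        if self.times.shape != (nt,):
            raise ParameterError(
                f"times length {self.times.shape} does not match intensity rows {nt}"
            )
        if np.any(np.diff(self.positions) <= 0):
            raise ParameterError("positions must be strictly increasing")
        if np.any(np.diff(self.times) <= 0):
            raise ParameterError("times must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ParameterError("intensity contains non-finite values")
        np.clip(self.intensity, 0.0, None, out=self.intensity)

    @property
    def n_times(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_positions(self) -> int:
        return self.intensity.shape[1]

    def profile(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(positions, intensity row)`` of frame ``i``."""
        return self.positions, self.intensity[i]

    # -- serialization ------------------------------------------------------

    def write_text(self, prefix: str | Path) -> tuple[Path, Path]:
        """Write ``<prefix>.tsv`` (rows = time) and a ``<prefix>.json`` sidecar.

        The sidecar carries the coordinate axes, the origin and any metadata
        (e.g. the simulation parameters that produced the kymograph).
        """
        prefix = Path(prefix)
        data_path = prefix.with_suffix(".tsv")
        meta_path = prefix.with_suffix(".json")
        np.savetxt(data_path, self.intensity, delimiter="\t", fmt="%.8g")
        sidecar = {
            "positions_um": self.positions.tolist(),
            "times_s": self.times.tolist(),
            "origin": self.origin,
            "meta": _jsonable(self.meta),
        }
        meta_path.write_text(json.dumps(sidecar, indent=1))
        return data_path, meta_path

    @classmethod
    def read_text(cls, prefix: str | Path) -> "Kymograph":
        prefix = Path(prefix)
        intensity = np.loadtxt(prefix.with_suffix(".tsv"), delimiter="\t", ndmin=2)
        sidecar = json.loads(prefix.with_suffix(".json").read_text())
        return cls(
            intensity=intensity,
            positions=np.asarray(sidecar["positions_um"], dtype=float),
            times=np.asarray(sidecar["times_s"], dtype=float),
            origin=float(sidecar.get("origin", 0.0)),
            meta=sidecar.get("meta", {}),
        )

    def write_tiff(self, path: str | Path) -> Path:
        """Export the per-frame 1D profiles as a multi-page float32 TIFF."""
        import tifffile

        path = Path(path)
        pages = self.intensity.astype(np.float32)[:, np.newaxis, :]
        tifffile.imwrite(path, pages)
        return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
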