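"""Gridded 2D spectrum container and its on-disk text format.

A spectrum plane is a real amplitude matrix (13C rows x 1H columns) with one
axis header per dimension.  ppm scales run high -> low with increasing index,
the standard NMR display convention.  On disk a grid is a plain-text matrix
(``<base>.mat.txt``, full float64 precision) plus a JSON sidecar header
(``<base>.json``); the writer/reader pair round-trips bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

__all__ = ["Axis", "SpectrumGrid", "write_grid", "read_grid"]


@dataclass(frozen=True)
class Axis:
    """One spectral dimension: carrier frequency and a ppm window."""

    sfrq_MHz: float
    ppm_max: float
    ppm_min: float
    npoints: int

    def __post_init__(self) -> None:
        if self.npoints < 2:
            raise ValueError("axis needs at least 2 points")
        if not self.ppm_max > self.ppm_min:
            raise ValueError("ppm_max must exceed ppm_min (axes run high->low)")
        if self.sfrq_MHz <= 0:
            raise ValueError("spectrometer frequency must be positive")

    @property
    def step_ppm(self) -> float:
        return (self.ppm_max - self.ppm_min) / (self.npoints - 1)

    @property
    def step_hz(self) -> float:
        return self.step_ppm * self.sfrq_MHz

    def ppm_scale(self) -> np.ndarray:
        """Strictly decreasing ppm value of every grid node."""
        return np.linspace(self.ppm_max, self.ppm_min, self.npoints)

    def ppm_to_index(self, ppm: float) -> float:
        """Fractional grid index of a ppm value (0 at ppm_max)."""
        return (self.ppm_max - ppm) / self.step_ppm

    def index_to_ppm(self, index: float) -> float:
        return self.ppm_max - index * self.step_ppm

    def contains(self, ppm: float, margin_points: int = 0) -> bool:
        m = margin_points * self.step_ppm
        return (self.ppm_min + m) <= ppm <= (self.ppm_max - m)


@dataclass
class SpectrumGrid:
    """Real 2D amplitude matrix with shape (c_axis.npoints, h_axis.npoints)."""

    data: np.ndarray
    c_axis: Axis
    h_axis: Axis

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.shape != (self.c_axis.npoints, self.h_axis.npoints):
            raise ValueError(
                f"matrix shape {self.data.shape} does not match axis headers "
                f"({self.c_axis.npoints}, {self.h_axis.npoints})"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


def write_grid(grid: SpectrumGrid, base: str | Path) -> tuple[Path, Path]:
    """Write ``<base>.mat.txt`` + ``<base>.json``; returns both paths."""
    base = Path(base)
    base.parent.mkdir(parents=True, exist_ok=True)
    mat_path = base.with_suffix(base.suffix + ".mat.txt")
    hdr_path = base.with_suffix(base.suffix + ".json")
    # %.17e preserves every float64 bit pattern through the text round trip
    np.savetxt(mat_path, grid.data, fmt="%.17e")
    header = {"c": asdict(grid.c_axis), "h": asdict(grid.h_axis)}
    hdr_path.write_text(json.dumps(header, indent=2, sort_keys=True) + "\n")
    return mat_path, hdr_path


def read_grid(base: str | Path) -> SpectrumGrid:
    base = Path(base)
    mat_path = base.with_suffix(base.suffix + ".mat.txt")
    hdr_path = base.with_suffix(base.suffix + ".json")
    header = json.loads(hdr_path.read_text())
    c_axis = Axis(**header["c"])
    h_axis = Axis(**header["h"])
    data = np.loadtxt(mat_path, ndmin=2)
    return SpectrumGrid(data=data, c_axis=c_axis, h_axis=h_axis)
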