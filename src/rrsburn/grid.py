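"""Wavenumber grids, spectra, and frame sequences.

Every stage of the analysis operates on intensity vectors defined on a
uniform wavenumber grid (cm^-1).  The raw detector readout spans
500-1800 cm^-1 at 2 cm^-1 spacing by default; the analysis itself runs on
the 600-1700 cm^-1 crop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["WavenumberGrid", "Spectrum", "SpectralLibrary", "FrameSequence"]


@dataclass(frozen=True)
class WavenumberGrid:
    """Uniform closed grid of Raman shifts in cm^-1."""

    start: float = 500.0
    stop: float = 1800.0
    step: float = 2.0

    def __post_init__(self) -> None:
        if not self.start < self.stop:
            raise ValueError(f"grid start {self.start} must be < stop {self.stop}")
        if self.step <= 0:
            raise ValueError(f"grid step must be positive, got {self.step}")

    @property
    def values(self) -> np.ndarray:
        n = int(round((self.stop - self.start) / self.step)) + 1
        return self.start + self.step * np.arange(n)

    def __len__(self) -> int:
        return int(round((self.stop - self.start) / self.step)) + 1

    def contains(self, wavenumber: float) -> bool:
        return self.start <= wavenumber <= self.stop

    @classmethod
    def from_values(cls, values: np.ndarray) -> "WavenumberGrid":
        """Build a grid from an explicit uniform wavenumber vector."""
        values = np.asarray(values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("need a 1-D vector of at least 2 wavenumbers")
        steps = np.diff(values)
        if not np.allclose(steps, steps[0], rtol=0, atol=1e-6):
            raise ValueError("wavenumber vector is not uniformly spaced")
        return cls(float(values[0]), float(values[-1]), float(steps[0]))


@dataclass
class Spectrum:
    """Intensity vector (detector counts, arbitrary units) on a grid."""

    grid: WavenumberGrid
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (len(self.grid),):
            raise ValueError(
                f"intensity vector length {self.intensities.shape} does not match "
                f"grid length {len(self.grid)}"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("spectrum contains non-finite intensities")

    @property
    def wavenumbers(self) -> np.ndarray:
        return self.grid.values


@dataclass
class SpectralLibrary(Spectrum):
    """Named max-normalized reference spectrum (e.g. HbO, HbR, mitochondria)."""

    name: str = ""


@dataclass
class FrameSequence:
    """Ordered stack of ~1 s acquisition frames sharing one grid.

    ``data`` is (n_frames, n_channels); an optional dark spectrum recorded
    with the probe in a dark chamber may ride along for subtraction.
    """

    grid: WavenumberGrid
    data: np.ndarray
    dark: Spectrum | None = field(default=None)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[1] != len(self.grid):
            raise ValueError(
                f"frame width {self.data.shape[1]} does not match grid length "
                f"{len(self.grid)}"
            )
        if self.dark is not None and self.dark.grid != self.grid:
            raise ValueError("dark spectrum grid does not match frame grid")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def frame(self, i: int) -> Spectrum:
        return Spectrum(self.grid, self.data[i])
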