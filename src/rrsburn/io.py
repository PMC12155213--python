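"""CSV interchange formats.

* library CSV: ``wavenumber_cm1,intensity`` (one file per library);
* frames CSV (long): ``frame_index,wavenumber_cm1,intensity``;
* wound metadata CSV: ``pig_id,wound_id,block_temp_c,contact_s,heal_pod,
  depth_um,epidermis_missing`` (empty heal_pod = unhealed at study end);
* coefficients CSV: one decomposed acquisition per row.

Grids are matched by exact wavenumber equality; a library on a different
uniform grid is resampled onto the measurement grid by linear
interpolation at load time.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .grid import FrameSequence, SpectralLibrary, WavenumberGrid

__all__ = [
    "write_library_csv", "read_library_csv",
    "write_frames_csv", "read_frames_csv",
    "write_wound_table_csv", "read_wound_table_csv",
    "resample_library",
]


def write_library_csv(lib: SpectralLibrary, path) -> None:
    pd.DataFrame(
        {"wavenumber_cm1": lib.wavenumbers, "intensity": lib.intensities}
    ).to_csv(path, index=False)


def read_library_csv(path, name: str | None = None) -> SpectralLibrary:
    df = pd.read_csv(path)
    for col in ("wavenumber_cm1", "intensity"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    grid = WavenumberGrid.from_values(df["wavenumber_cm1"].to_numpy())
    return SpectralLibrary(
        grid, df["intensity"].to_numpy(dtype=float),
        name=name or Path(path).stem,
    )


def resample_library(lib: SpectralLibrary, grid: WavenumberGrid) -> SpectralLibrary:
    """Linear-interpolation resampling onto a measurement grid."""
    if lib.grid == grid:
        return lib
    y = np.interp(grid.values, lib.wavenumbers, lib.intensities)
    return SpectralLibrary(grid, y, name=lib.name)


def write_frames_csv(seq: FrameSequence, path) -> None:
    n_frames, n_chan = seq.data.shape
    pd.DataFrame(
        {
            "frame_index": np.repeat(np.arange(n_frames), n_chan),
            "wavenumber_cm1": np.tile(seq.grid.values, n_frames),
            "intensity": seq.data.ravel(),
        }
    ).to_csv(path, index=False)


def read_frames_csv(path) -> FrameSequence:
    df = pd.read_csv(path)
    for col in ("frame_index", "wavenumber_cm1", "intensity"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    frames = []
    grid = None
    for _, g in df.groupby("frame_index", sort=True):
        w = g["wavenumber_cm1"].to_numpy()
        this_grid = WavenumberGrid.from_values(w)
        if grid is None:
            grid = this_grid
        elif this_grid != grid:
            raise ValueError(f"{path}: frames do not share one grid")
        frames.append(g["intensity"].to_numpy(dtype=float))
    if grid is None:
        raise ValueError(f"{path}: no frames found")
    return FrameSequence(grid, np.vstack(frames))


WOUND_COLUMNS = [
    "pig_id", "wound_id", "block_temp_c", "contact_s",
    "heal_pod", "depth_um", "epidermis_missing",
]


def write_wound_table_csv(df: pd.DataFrame, path) -> None:
    df.loc[:, WOUND_COLUMNS].to_csv(path, index=False)


def read_wound_table_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in WOUND_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing wound-table columns {missing}")
    df["heal_pod"] = df["heal_pod"].astype("Int64")
    df["epidermis_missing"] = df["epidermis_missing"].astype(bool)
    return df
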