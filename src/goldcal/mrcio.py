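"""Minimal MRC2014 image I/O built on gemmi's CCP4/MRC map support.

Micrographs are stored as 2D images (or stacks along the slowest axis);
the header pixel size is encoded, as MRC2014 specifies, by the unit-cell
edge divided by the grid sampling.  Reading accepts modes 0/1/2/6 (int8,
int16, float32, uint16 — gemmi converts to float); writing always emits
mode 2 (float32).
"""

from __future__ import annotations

from pathlib import Path

import gemmi
import numpy as np


def read_mrc(path: str | Path) -> tuple[np.ndarray, float]:
    """Read an MRC file; returns (data, pixel_size_Å).

    ``data`` has shape (ny, nx) for a single image or (nz, ny, nx) for a
    stack.  The pixel size is taken from the x sampling; 0.0 if the header
    cell is unset.
    """
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise IOError(f"cannot read MRC file {path}: {exc}") from exc
    # gemmi grid arrays index as [x, y, z]; transpose to (z, y, x)
    arr = np.array(m.grid, copy=True).transpose(2, 1, 0).astype(np.float32)
    nx = m.grid.nu
    cell_a = m.grid.unit_cell.a
    pixel = cell_a / nx if nx and cell_a else 0.0
    if arr.shape[0] == 1:
        arr = arr[0]
    return arr, float(pixel)


def write_mrc(path: str | Path, data: np.ndarray, pixel_size: float) -> None:
    """Write a 2D image or a (nz, ny, nx) stack as a mode-2 MRC2014 file."""
    data = np.asarray(data, dtype=np.float32)
    if data.ndim == 2:
        data = data[None, :, :]
    if data.ndim != 3:
        raise ValueError(f"expected 2D or 3D array, got shape {data.shape}")
    nz, ny, nx = data.shape
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(data.transpose(2, 1, 0)))
    m.grid.unit_cell = gemmi.UnitCell(
        nx * pixel_size, ny * pixel_size, nz * pixel_size, 90.0, 90.0, 90.0
    )
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))
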