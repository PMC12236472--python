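"""Reading, standardizing, partitioning and re-stitching cryo-EM density volumes.

Voxel arrays are indexed ``(z, y, x)`` throughout the package, so that grid
index ``i`` runs along the physical ``z`` axis, ``j`` along ``y`` and ``k``
along ``x``.  File I/O converts explicitly between this convention and the
CCP4/MRC column/row/section layout.

The standardization pipeline mirrors common practice for map-to-model deep
learning: trilinear resampling to a 1 Å grid, then median background
subtraction, upper-tail percentile clipping and min-max scaling to [0, 1].
Whole maps are processed by tiling them into non-overlapping cores with a
fixed context margin on every face; per-window network outputs are stitched
back by writing only each core.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
from scipy.ndimage import map_coordinates


class MapFormatError(ValueError):
    """Raised when a density-map file cannot be interpreted."""


@dataclass
class DensityMap:
    """A scalar density volume with physical metadata.

    Attributes
    ----------
    data:
        3-D float array indexed ``(z, y, x)``.
    origin:
        Physical position of voxel ``(0, 0, 0)`` as ``(x, y, z)`` in Å.
    voxel_size:
        Å per voxel along ``(x, y, z)``; all components must be positive.
    resolution:
        Optional nominal map resolution in Å (metadata only).
    """

    data: np.ndarray
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    resolution: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise MapFormatError(
                f"density data must be 3-D, got shape {self.data.shape}"
            )
        if any(v <= 0 for v in self.voxel_size):
            raise MapFormatError(f"voxel_size must be positive, got {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # (nz, ny, nx)


def read_map(path) -> DensityMap:
    """Read an MRC/CCP4 volume into a :class:`DensityMap`.

    The grid is reordered to X-fastest axes by gemmi and then transposed to
    the internal ``(z, y, x)`` indexing.  The physical origin is taken from
    the MRC ``ORIGIN`` record when set, otherwise from ``NXSTART/NYSTART/
    NZSTART`` scaled by the voxel size.
    """
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise MapFormatError(f"cannot read map file {path!r}: {exc}") from exc
    nstart = (m.header_i32(5), m.header_i32(6), m.header_i32(7))
    m.setup(0.0)
    arr = np.array(m.grid, copy=True)  # (nx, ny, nz)
    if arr.ndim != 3 or min(arr.shape) < 1:
        raise MapFormatError(f"map data is not a 3-D volume: shape {arr.shape}")
    if min(arr.shape) == 1:
        raise MapFormatError(
            f"map field 'data' is degenerate (shape {arr.shape}); a 3-D volume is required"
        )
    cell = m.grid.unit_cell
    voxel = (cell.a / m.grid.nu, cell.b / m.grid.nv, cell.c / m.grid.nw)
    if any(v <= 0 for v in voxel):
        raise MapFormatError(f"map field 'voxel_size' is invalid: {voxel}")
    origin = (m.header_float(50), m.header_float(51), m.header_float(52))
    if origin == (0.0, 0.0, 0.0) and any(nstart):
        origin = tuple(n * v for n, v in zip(nstart, voxel))
    resolution = None
    return DensityMap(
        data=arr.transpose(2, 1, 0).astype(np.float32),
        origin=origin,
        voxel_size=voxel,
        resolution=resolution,
    )


def write_map(dmap: DensityMap, path) -> None:
    """Write a :class:`DensityMap` as a mode-2 (float32) CCP4/MRC file."""
    nz, ny, nx = dmap.shape
    vx, vy, vz = dmap.voxel_size
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(dmap.data.transpose(2, 1, 0)))
    m.grid.unit_cell = gemmi.UnitCell(nx * vx, ny * vy, nz * vz, 90.0, 90.0, 90.0)
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header()
    ox, oy, oz = dmap.origin
    m.set_header_float(50, float(ox))
    m.set_header_float(51, float(oy))
    m.set_header_float(52, float(oz))
    m.write_ccp4_map(str(path))


def resample_to_unit_voxel(dmap: DensityMap) -> DensityMap:
    """Trilinearly resample a map onto a 1 Å isotropic grid.

    The output grid starts at the same origin and spans the same physical
    extent; the resampled dimension along each axis is ``round(extent) + 1``
    so that both end planes remain covered.
    """
    if all(abs(v - 1.0) < 1e-9 for v in dmap.voxel_size):
        return replace(dmap, data=dmap.data.copy())
    nz, ny, nx = dmap.shape
    vx, vy, vz = dmap.voxel_size
    # extent in Å along each axis; new sampling at integer Å offsets
    new_nz = int(round((nz - 1) * vz)) + 1
    new_ny = int(round((ny - 1) * vy)) + 1
    new_nx = int(round((nx - 1) * vx)) + 1
    zi, yi, xi = np.meshgrid(
        np.arange(new_nz) / vz,
        np.arange(new_ny) / vy,
        np.arange(new_nx) / vx,
        indexing="ij",
    )
    out = map_coordinates(
        dmap.data.astype(np.float64),
        np.stack([zi, yi, xi]),
        order=1,
        mode="nearest",
    ).astype(np.float32)
    return DensityMap(
        data=out,
        origin=dmap.origin,
        voxel_size=(1.0, 1.0, 1.0),
        resolution=dmap.resolution,
    )


def normalize_map(dmap: DensityMap) -> DensityMap:
    """Standardize voxel values to [0, 1].

    Pipeline: subtract the median; clip values above the 99.9th percentile of
    the median-subtracted data down to that percentile; floor negatives at 0;
    min-max scale.  An all-constant map degenerates to all zeros.
    """
    data = dmap.data.astype(np.float64)
    if not np.all(np.isfinite(data)):
        raise ValueError("map contains non-finite values")
    data = data - np.median(data)
    hi = np.percentile(data, 99.9)
    data = np.minimum(data, hi)
    data = np.maximum(data, 0.0)
    peak = data.max()
    if peak <= 0.0:
        out = np.zeros_like(data, dtype=np.float32)
    else:
        out = (data / peak).astype(np.float32)
    return replace(dmap, data=out)


CORE_SIZE = 48
PAD = 8
WINDOW = CORE_SIZE + 2 * PAD  # 64


@dataclass
class GridBatch:
    """Tiling of a full map into fixed-size processing windows.

    ``windows[n]`` is a ``window_size³`` volume whose central
    ``core_size³`` block covers the map voxels starting at
    ``core_offsets[n]`` (``(i, j, k)`` in the full array); context outside
    the map is zero-filled.
    """

    windows: list[np.ndarray] = field(default_factory=list)
    core_offsets: list[tuple[int, int, int]] = field(default_factory=list)
    full_shape: tuple[int, int, int] = (0, 0, 0)
    core_size: int = CORE_SIZE
    pad: int = PAD

    @property
    def window_size(self) -> int:
        return self.core_size + 2 * self.pad


def partition_grids(
    volume: DensityMap | np.ndarray, core_size: int = CORE_SIZE, pad: int = PAD
) -> GridBatch:
    """Tile a volume into non-overlapping cores with zero-padded context.

    Cores of ``core_size³`` voxels tile the map starting at its origin
    corner; each is wrapped with ``pad`` voxels of context on all six faces
    to form the processing window.  Partial tiles at the far edges and
    out-of-map context are zero-filled.
    """
    data = volume.data if isinstance(volume, DensityMap) else np.asarray(volume)
    if data.ndim != 3 or data.size == 0:
        raise ValueError(f"expected a non-empty 3-D volume, got shape {data.shape}")
    full_shape = data.shape
    n_tiles = [math.ceil(s / core_size) for s in full_shape]
    padded = np.zeros(
        tuple(n * core_size + 2 * pad for n in n_tiles), dtype=data.dtype
    )
    padded[
        pad : pad + full_shape[0],
        pad : pad + full_shape[1],
        pad : pad + full_shape[2],
    ] = data
    batch = GridBatch(full_shape=full_shape, core_size=core_size, pad=pad)
    w = core_size + 2 * pad
    for ti in range(n_tiles[0]):
        for tj in range(n_tiles[1]):
            for tk in range(n_tiles[2]):
                i0, j0, k0 = ti * core_size, tj * core_size, tk * core_size
                batch.windows.append(
                    padded[i0 : i0 + w, j0 : j0 + w, k0 : k0 + w].copy()
                )
                batch.core_offsets.append((i0, j0, k0))
    return batch


def stitch_volumes(batch_outputs: list[np.ndarray], batch: GridBatch) -> np.ndarray:
    """Re-assemble per-window outputs into a full-map volume.

    Only the central core of each window is written at its core offset; the
    result is cropped to the original map shape.  Outputs may carry a leading
    channel axis, in which case the stitched volume does too.
    """
    if len(batch_outputs) != len(batch.windows):
        raise ValueError(
            f"expected {len(batch.windows)} window outputs, got {len(batch_outputs)}"
        )
    w, c, p = batch.window_size, batch.core_size, batch.pad
    first = np.asarray(batch_outputs[0])
    channels = None if first.ndim == 3 else first.shape[0]
    out_shape = batch.full_shape if channels is None else (channels,) + batch.full_shape
    out = np.zeros(out_shape, dtype=first.dtype)
    for win_out, (i0, j0, k0) in zip(batch_outputs, batch.core_offsets):
        win_out = np.asarray(win_out)
        expected = (w, w, w) if channels is None else (channels, w, w, w)
        if win_out.shape != expected:
            raise ValueError(
                f"window output shape {win_out.shape} does not match expected {expected}"
            )
        core = win_out[..., p : p + c, p : p + c, p : p + c]
        di = min(c, batch.full_shape[0] - i0)
        dj = min(c, batch.full_shape[1] - j0)
        dk = min(c, batch.full_shape[2] - k0)
        out[..., i0 : i0 + di, j0 : j0 + dj, k0 : k0 + dk] = core[..., :di, :dj, :dk]
    return out
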