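"""Volume, table and mesh I/O with explicit physical spacing.

Every 3D array in this package is indexed ``(z, y, x)`` and carries its
voxel spacing in nanometres.  FIB-SEM stacks are strongly anisotropic
(typically ~10 nm in plane and ~90 nm between sections), so spacing is
never optional: readers fail loudly when a file carries no spacing
metadata and no override is given, instead of silently assuming cubes.

Supported volume containers are multipage TIFF (ImageJ-style metadata
dialect) and MRC2014.  The MRC codec here is a deliberately small
implementation of the public header layout (modes 0, 1, 2 and 6) — cell
dimensions in the header are Ångström per the format convention and are
converted to nm at the boundary.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
import trimesh
from skimage import measure

__all__ = [
    "VoxelGrid",
    "read_stack",
    "write_stack",
    "effective_section_spacing",
    "write_mesh",
    "mesh_from_mask",
]


@dataclass
class VoxelGrid:
    """A 3D scalar volume with anisotropic physical spacing.

    Parameters
    ----------
    data:
        Array of shape ``(nz, ny, nx)``.
    spacing:
        Voxel spacing ``(dz, dy, dx)`` in nm.  The physical position of
        voxel ``(i, j, k)`` (its centre) is ``origin + (i*dz, j*dy, k*dx)``.
    origin:
        Physical offset of voxel ``(0, 0, 0)`` in nm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"VoxelGrid data must be 3D, got {self.data.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive numbers, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_nm3(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx

    def physical_coords(self, indices: np.ndarray) -> np.ndarray:
        """Map fractional voxel indices (N, 3) to physical nm coordinates."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)

    def voxel_index(self, coords_nm: np.ndarray) -> np.ndarray:
        """Map physical nm coordinates (N, 3) to the containing voxel index."""
        xyz = np.atleast_2d(np.asarray(coords_nm, dtype=float))
        idx = np.rint((xyz - np.asarray(self.origin)) / np.asarray(self.spacing))
        return idx.astype(int)


# ---------------------------------------------------------------------------
# TIFF


def _write_tiff(grid: VoxelGrid, path: Path) -> None:
    dz, dy, dx = grid.spacing
    data = grid.data
    if data.dtype == bool:
        data = data.astype(np.uint8) * 255
    # ImageJ dialect: XY resolution in pixels per unit, z step in metadata.
    tifffile.imwrite(
        path,
        data,
        imagej=data.dtype in (np.dtype(np.uint8), np.dtype(np.uint16), np.dtype(np.float32)),
        resolution=(1.0 / dx, 1.0 / dy),
        metadata={"spacing": dz, "unit": "nm", "axes": "ZYX"},
    )


def _read_tiff(path: Path) -> tuple[np.ndarray, tuple[float, float, float] | None]:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        if data.ndim == 2:
            data = data[None]
        if data.ndim != 3:
            raise ValueError(f"{path}: expected a single-channel stack, got shape {data.shape}")
        spacing = None
        meta = tf.imagej_metadata
        page = tf.pages[0]
        try:
            xres = page.tags["XResolution"].value
            yres = page.tags["YResolution"].value
            dx = xres[1] / xres[0]
            dy = yres[1] / yres[0]
        except (KeyError, ZeroDivisionError):
            dx = dy = None
        if meta is not None and "spacing" in meta and dx is not None:
            spacing = (float(meta["spacing"]), float(dy), float(dx))
    return data, spacing


# ---------------------------------------------------------------------------
# MRC (minimal MRC2014 codec)

_MRC_MODES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}
_MRC_MODES_INV = {np.dtype(v): k for k, v in _MRC_MODES.items()}


def _write_mrc(grid: VoxelGrid, path: Path) -> None:
    data = grid.data
    if data.dtype == bool:
        data = data.astype(np.int8)
    if data.dtype not in _MRC_MODES_INV:
        data = data.astype(np.float32)
    mode = _MRC_MODES_INV[data.dtype]
    nz, ny, nx = data.shape
    dz, dy, dx = grid.spacing
    header = bytearray(1024)
    struct.pack_into("<3i", header, 0, nx, ny, nz)       # NX NY NZ
    struct.pack_into("<i", header, 12, mode)             # MODE
    struct.pack_into("<3i", header, 28, nx, ny, nz)      # MX MY MZ
    # CELLA in Ångström (1 nm = 10 Å)
    struct.pack_into("<3f", header, 40, nx * dx * 10.0, ny * dy * 10.0, nz * dz * 10.0)
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", header, 64, 1, 2, 3)         # MAPC MAPR MAPS
    struct.pack_into("<3f", header, 76, float(data.min()), float(data.max()), float(data.mean()))
    header[208:212] = b"MAP "
    header[212:216] = b"\x44\x44\x00\x00"                # little-endian machine stamp
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(np.ascontiguousarray(data).tobytes())


def _read_mrc(path: Path, angstrom: bool = True) -> tuple[np.ndarray, tuple[float, float, float] | None]:
    with open(path, "rb") as fh:
        header = fh.read(1024)
        nx, ny, nz = struct.unpack_from("<3i", header, 0)
        (mode,) = struct.unpack_from("<i", header, 12)
        mx, my, mz = struct.unpack_from("<3i", header, 28)
        ca, cb, cc = struct.unpack_from("<3f", header, 40)
        if mode not in _MRC_MODES:
            raise ValueError(f"{path}: unsupported MRC mode {mode}")
        dtype = np.dtype(_MRC_MODES[mode])
        data = np.frombuffer(fh.read(nx * ny * nz * dtype.itemsize), dtype=dtype)
    data = data.reshape(nz, ny, nx).copy()
    spacing = None
    if ca > 0 and cb > 0 and cc > 0 and mx > 0 and my > 0 and mz > 0:
        scale = 0.1 if angstrom else 1.0  # header cell is Å by convention
        spacing = (cc / mz * scale, cb / my * scale, ca / mx * scale)
    return data, spacing


# ---------------------------------------------------------------------------
# Public stack API


def write_stack(grid: VoxelGrid, path: str | Path) -> Path:
    """Write a :class:`VoxelGrid` to multipage TIFF or MRC, inferred from suffix."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        _write_tiff(grid, path)
    elif suffix in (".mrc", ".rec", ".map"):
        _write_mrc(grid, path)
    else:
        raise ValueError(f"unsupported stack format: {path.suffix}")
    return path


def read_stack(
    path: str | Path,
    spacing_override: tuple[float, float, float] | None = None,
    mrc_cell_in_angstrom: bool = True,
) -> VoxelGrid:
    """Read a multipage TIFF or MRC stack into a :class:`VoxelGrid`.

    Spacing comes from file metadata when present; ``spacing_override``
    (nm, ``(dz, dy, dx)``) takes precedence when given.  A file with no
    usable spacing metadata and no override is an error — spacing is
    never silently defaulted.  ``mrc_cell_in_angstrom`` documents the
    unit of the MRC cell header (the format standard is Å); pass False
    for files mis-declared in nm.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        data, spacing = _read_tiff(path)
    elif suffix in (".mrc", ".rec", ".map"):
        data, spacing = _read_mrc(path, angstrom=mrc_cell_in_angstrom)
    else:
        raise ValueError(f"unsupported stack format: {path.suffix}")
    if spacing_override is not None:
        spacing = tuple(float(s) for s in spacing_override)
    if spacing is None:
        raise ValueError(
            f"{path} carries no voxel-spacing metadata; pass spacing_override=(dz, dy, dx) in nm"
        )
    return VoxelGrid(data=data, spacing=spacing)


# ---------------------------------------------------------------------------
# Acquisition geometry


def effective_section_spacing(nominal_mill_nm: float, imaging_stride: int) -> float:
    """Effective z spacing of an imaged FIB-SEM series, in nm.

    Slice-and-view acquisitions often mill thinner than they image: with
    a 30 nm nominal mill and every third face imaged, the imaged series
    has 90 nm between sections.

    Parameters
    ----------
    nominal_mill_nm:
        Nominal milling thickness per cycle (nm), > 0.
    imaging_stride:
        Every ``imaging_stride``-th exposed face is imaged (integer ≥ 1).
    """
    if nominal_mill_nm <= 0:
        raise ValueError("nominal milling thickness must be positive")
    stride = imaging_stride
    if isinstance(stride, float):
        if not float(stride).is_integer():
            raise ValueError(f"imaging stride must be an integer, got {imaging_stride}")
        stride = int(stride)
    if not isinstance(stride, (int, np.integer)) or stride < 1:
        raise ValueError(f"imaging stride must be a positive integer, got {imaging_stride}")
    return float(nominal_mill_nm) * int(stride)


# ---------------------------------------------------------------------------
# Meshes


def mesh_from_mask(
    mask: np.ndarray,
    spacing: tuple[float, float, float],
    smooth_sigma_vox: float = 1.5,
) -> trimesh.Trimesh:
    """Triangulate the 0.5-isosurface of a binary mask in physical nm.

    The mask is zero-padded by one voxel per face so the surface is
    always closed, then lightly Gaussian-smoothed (``smooth_sigma_vox``
    voxels, isotropic in index space) before marching cubes to suppress
    the staircase bias of binary voxelization.  Vertices are returned in
    ``(z, y, x)`` nm coordinates of the unpadded volume.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("cannot mesh an empty mask")
    from scipy.ndimage import gaussian_filter

    padded = np.pad(mask, 1).astype(np.float32)
    if smooth_sigma_vox > 0:
        padded = gaussian_filter(padded, smooth_sigma_vox)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=spacing)
    verts -= np.asarray(spacing)  # undo the 1-voxel pad
    return trimesh.Trimesh(vertices=verts, faces=faces, process=False)


def write_mesh(
    mask: np.ndarray,
    spacing: tuple[float, float, float],
    path: str | Path,
) -> trimesh.Trimesh:
    """Mesh a binary mask and write OBJ or STL (chosen by suffix)."""
    path = Path(path)
    mesh = mesh_from_mask(mask, spacing)
    suffix = path.suffix.lower()
    if suffix not in (".obj", ".stl"):
        raise ValueError(f"unsupported mesh format: {path.suffix}")
    mesh.export(path)
    return mesh
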