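"""Volume containers and MetaImage / multi-page TIFF round-trip I/O.

Arrays are stored z-major (``shape == (nz, ny, nx)``) with isotropic spacing
in mm and a physical origin giving the coordinate of voxel center (0, 0, 0).
``dims`` reports voxel counts in (x, y, z) order, following the MetaImage
convention.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "VoxelVolume",
    "VolumeIOError",
    "read_volume",
    "write_volume",
    "voxel_centers",
]


class VolumeIOError(IOError):
    """Unknown format or malformed volume file."""


@dataclass
class VoxelVolume:
    """A 3D scalar volume with spacing metadata."""

    values: np.ndarray  # (nz, ny, nx)
    spacing: float  # mm / voxel, isotropic
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)  # (x, y, z) mm

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.values.shape}")
        if not self.spacing > 0:
            raise ValueError(f"spacing must be > 0, got {self.spacing}")
        if np.issubdtype(self.values.dtype, np.floating) and not np.all(
            np.isfinite(self.values)
        ):
            raise ValueError("grayvalues must be finite")

    @property
    def dims(self) -> tuple[int, int, int]:
        """(nx, ny, nz) voxel counts."""
        nz, ny, nx = self.values.shape
        return (nx, ny, nz)

    @property
    def voxel_volume_mm3(self) -> float:
        return self.spacing**3

    def physical_center_xy(self) -> tuple[float, float]:
        nz, ny, nx = self.values.shape
        return (
            self.origin[0] + (nx - 1) / 2.0 * self.spacing,
            self.origin[1] + (ny - 1) / 2.0 * self.spacing,
        )


def voxel_centers(shape: tuple[int, int, int], spacing: float,
                  origin=(0.0, 0.0, 0.0)):
    """Open-grid physical coordinates (z, y, x arrays) of voxel centers."""
    nz, ny, nx = shape
    z = origin[2] + spacing * np.arange(nz)
    y = origin[1] + spacing * np.arange(ny)
    x = origin[0] + spacing * np.arange(nx)
    return np.ix_(z, y, x)


# ---------------------------------------------------------------------------
# MetaImage (.mhd + .raw): plain-text header next to a little-endian raw blob.

_MET_TYPES = {
    "MET_UCHAR": np.uint8,
    "MET_CHAR": np.int8,
    "MET_USHORT": np.uint16,
    "MET_SHORT": np.int16,
    "MET_UINT": np.uint32,
    "MET_INT": np.int32,
    "MET_FLOAT": np.float32,
    "MET_DOUBLE": np.float64,
}
_NP_TO_MET = {np.dtype(v): k for k, v in _MET_TYPES.items()}


def _write_mhd(volume: VoxelVolume, path: Path) -> None:
    dtype = np.dtype(volume.values.dtype)
    if dtype not in _NP_TO_MET:
        raise VolumeIOError(f"dtype {dtype} not supported by MetaImage writer")
    raw_name = path.with_suffix(".raw").name
    nx, ny, nz = volume.dims
    header = "\n".join(
        [
            "ObjectType = Image",
            "NDims = 3",
            "BinaryData = True",
            "BinaryDataByteOrderMSB = False",
            "CompressedData = False",
            f"DimSize = {nx} {ny} {nz}",
            f"ElementSpacing = {volume.spacing:.6f} {volume.spacing:.6f} {volume.spacing:.6f}",
            f"Offset = {volume.origin[0]:.6f} {volume.origin[1]:.6f} {volume.origin[2]:.6f}",
            f"ElementType = {_NP_TO_MET[dtype]}",
            f"ElementDataFile = {raw_name}",
            "",
        ]
    )
    path.write_text(header)
    vals = volume.values.astype(dtype.newbyteorder("<"), copy=False)
    vals.tofile(path.with_suffix(".raw"))


def _read_mhd(path: Path) -> VoxelVolume:
    fields: dict[str, str] = {}
    try:
        for line in path.read_text().splitlines():
            if "=" in line:
                key, _, val = line.partition("=")
                fields[key.strip()] = val.strip()
    except UnicodeDecodeError as exc:
        raise VolumeIOError(f"{path}: not a text MetaImage header") from exc
    try:
        dim = [int(v) for v in fields["DimSize"].split()]
        spacing = [float(v) for v in fields["ElementSpacing"].split()]
        met_type = fields["ElementType"]
        data_file = fields["ElementDataFile"]
    except KeyError as exc:
        raise VolumeIOError(f"{path}: missing MetaImage header key {exc}") from exc
    if len(dim) != 3:
        raise VolumeIOError(f"{path}: expected 3D volume, DimSize = {dim}")
    if met_type not in _MET_TYPES:
        raise VolumeIOError(f"{path}: unsupported ElementType {met_type}")
    if len(set(np.round(spacing, 9))) != 1:
        raise VolumeIOError(f"{path}: anisotropic spacing {spacing} not supported")
    offset = [float(v) for v in fields.get("Offset", "0 0 0").split()]
    nx, ny, nz = dim
    raw_path = path.parent / data_file
    if not raw_path.exists():
        raise VolumeIOError(f"{path}: data file {data_file} not found")
    dtype = np.dtype(_MET_TYPES[met_type]).newbyteorder("<")
    data = np.fromfile(raw_path, dtype=dtype)
    if data.size != nx * ny * nz:
        raise VolumeIOError(
            f"{path}: raw size {data.size} does not match DimSize {dim}"
        )
    values = data.reshape(nz, ny, nx).astype(_MET_TYPES[met_type])
    return VoxelVolume(values=values, spacing=spacing[0], origin=tuple(offset))


# ---------------------------------------------------------------------------
# Multi-page TIFF: one page per z slice; spacing/origin in the description.

def _write_tiff(volume: VoxelVolume, path: Path) -> None:
    tifffile.imwrite(
        path,
        volume.values,
        metadata={
            "spacing_mm": round(volume.spacing, 6),
            "origin_mm": [round(v, 6) for v in volume.origin],
            "axes": "ZYX",
        },
    )


def _read_tiff(path: Path) -> VoxelVolume:
    try:
        with tifffile.TiffFile(path) as tf:
            values = tf.asarray()
            meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    except tifffile.TiffFileError as exc:
        raise VolumeIOError(f"{path}: unreadable TIFF ({exc})") from exc
    if values.ndim == 2:
        values = values[None]
    spacing = float(meta.get("spacing_mm", 1.0))
    origin = tuple(float(v) for v in meta.get("origin_mm", (0.0, 0.0, 0.0)))
    return VoxelVolume(values=values, spacing=spacing, origin=origin)


# ---------------------------------------------------------------------------

def write_volume(volume: VoxelVolume, path: str | os.PathLike) -> Path:
    """Write a volume; format chosen by extension (.mhd, .tif/.tiff)."""
    path = Path(path)
    ext = path.suffix.lower()
    if ext == ".mhd":
        _write_mhd(volume, path)
    elif ext in (".tif", ".tiff"):
        _write_tiff(volume, path)
    else:
        raise VolumeIOError(
            f"unknown volume extension {ext!r}; use .mhd or .tif/.tiff"
        )
    return path


def read_volume(path: str | os.PathLike) -> VoxelVolume:
    """Read a volume written by :func:`write_volume`."""
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"no such file: {path}")
    ext = path.suffix.lower()
    if ext == ".mhd":
        return _read_mhd(path)
    if ext in (".tif", ".tiff"):
        return _read_tiff(path)
    raise VolumeIOError(f"unknown volume extension {ext!r}; use .mhd or .tif/.tiff")
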