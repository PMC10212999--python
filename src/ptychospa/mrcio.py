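"""Minimal MRC2014 I/O (mode 2, little-endian float32).

Covers exactly what the pipeline needs: single 2D images, image stacks
(``.mrcs``) and 3D volumes, with the voxel size carried in the cell header.
Lengths in the MRC header are in Angstrom per the format; the package API is
in nm and the conversion happens here.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from ptychospa.core import Volume3D

_HEADER_BYTES = 1024
_NM_TO_ANG = 10.0
# MRC2014 ispg: 0 = image/stack, 1 = volume
_ISPG_STACK = 0
_ISPG_VOLUME = 1


def _pack_header(shape_zyx, voxel_size_nm: float, ispg: int, data: np.ndarray) -> bytes:
    nz, ny, nx = shape_zyx
    cell = (
        nx * voxel_size_nm * _NM_TO_ANG,
        ny * voxel_size_nm * _NM_TO_ANG,
        nz * voxel_size_nm * _NM_TO_ANG,
    )
    h = bytearray(_HEADER_BYTES)
    struct.pack_into("<3i", h, 0, nx, ny, nz)
    struct.pack_into("<i", h, 12, 2)  # mode 2 = float32
    struct.pack_into("<3i", h, 28, nx, ny, nz)  # mx, my, mz
    struct.pack_into("<3f", h, 40, *cell)
    struct.pack_into("<3f", h, 52, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", h, 64, 1, 2, 3)  # mapc, mapr, maps
    struct.pack_into("<3f", h, 76, float(data.min()), float(data.max()), float(data.mean()))
    struct.pack_into("<i", h, 88, ispg)
    struct.pack_into("<i", h, 108, 20140)  # nversion
    h[208:212] = b"MAP "
    h[212:216] = bytes((0x44, 0x44, 0x00, 0x00))  # little-endian machine stamp
    struct.pack_into("<f", h, 216, float(data.std()))
    struct.pack_into("<i", h, 220, 1)
    h[224 : 224 + 80] = b"ptychospa".ljust(80)
    return bytes(h)


def _read_header(raw: bytes):
    nx, ny, nz = struct.unpack_from("<3i", raw, 0)
    (mode,) = struct.unpack_from("<i", raw, 12)
    mx, my, mz = struct.unpack_from("<3i", raw, 28)
    cellx, celly, cellz = struct.unpack_from("<3f", raw, 40)
    if raw[208:212] not in (b"MAP ", b"MAP\x00"):
        raise ValueError("not an MRC2014 file (missing MAP stamp)")
    if mode != 2:
        raise ValueError(f"only mode 2 (float32) supported, got mode {mode}")
    voxel = cellx / mx / _NM_TO_ANG if mx else 1.0
    return (nz, ny, nx), voxel


def write_volume(path, vol: Volume3D) -> None:
    """Write a :class:`Volume3D` as an MRC mode-2 map."""
    data = np.ascontiguousarray(vol.values, dtype="<f4")
    with open(path, "wb") as fh:
        fh.write(_pack_header(data.shape, vol.voxel_size, _ISPG_VOLUME, data))
        fh.write(data.tobytes())


def read_volume(path) -> Volume3D:
    raw = Path(path).read_bytes()
    shape, voxel = _read_header(raw[:_HEADER_BYTES])
    data = np.frombuffer(raw[_HEADER_BYTES:], dtype="<f4", count=int(np.prod(shape)))
    return Volume3D(data.reshape(shape).astype(np.float64), voxel)


def write_image(path, image: np.ndarray, pixel_size_nm: float) -> None:
    """Write a single 2D image as an MRC mode-2 file."""
    image = np.asarray(image, dtype="<f4")
    if image.ndim != 2:
        raise ValueError("write_image expects a 2D array")
    data = np.ascontiguousarray(image[None])
    with open(path, "wb") as fh:
        fh.write(_pack_header(data.shape, pixel_size_nm, _ISPG_STACK, data))
        fh.write(data.tobytes())


def write_stack(path, boxes: np.ndarray, pixel_size_nm: float) -> None:
    """Write an ``(N, box, box)`` particle stack as MRCS."""
    boxes = np.ascontiguousarray(boxes, dtype="<f4")
    if boxes.ndim != 3:
        raise ValueError("write_stack expects an (N, box, box) array")
    with open(path, "wb") as fh:
        fh.write(_pack_header(boxes.shape, pixel_size_nm, _ISPG_STACK, boxes))
        fh.write(boxes.tobytes())


def read_stack(path):
    """Read an MRC/MRCS file as ``(array (nz, ny, nx), pixel_size_nm)``."""
    raw = Path(path).read_bytes()
    shape, voxel = _read_header(raw[:_HEADER_BYTES])
    data = np.frombuffer(raw[_HEADER_BYTES:], dtype="<f4", count=int(np.prod(shape)))
    return data.reshape(shape).astype(np.float64), voxel
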