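"""MRC2014 and tilt-angle file I/O.

Implements the small corner of the MRC2014 standard this package needs:
mode 2 (32-bit float) images and stacks, with byte order auto-detected from
the header and extended headers skipped.  Tilt angles travel in IMOD-style
``.rawtlt`` files (one decimal degree value per line).  All writes are
atomic (write to a temporary file, then rename) so interrupted runs never
leave truncated files behind.
"""

from __future__ import annotations

import os
import struct
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np


class FormatError(ValueError):
    """File does not conform to the expected format."""


_HEADER_SIZE = 1024
_MODE_FLOAT32 = 2


@dataclass
class ProjectionStack:
    """An aligned tilt series: one (1-D or 2-D) projection per tilt angle."""

    data: np.ndarray     # (n_proj, n_bins) or (n_proj, ny, nx)
    angles: np.ndarray   # degrees, one per projection
    pixel_size: float = 1.0
    provenance: str = ""

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=np.float64)
        a = np.asarray(self.angles, dtype=np.float64)
        if d.shape[0] != a.size:
            raise FormatError(
                f"{d.shape[0]} projections but {a.size} tilt angles")
        if np.unique(a).size != a.size:
            raise FormatError("tilt angles must be unique")
        self.data = d
        self.angles = a

    @property
    def n_projections(self) -> int:
        return self.data.shape[0]


def _atomic_write(path: Union[str, Path], payload: bytes) -> None:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "wb") as fh:
            fh.write(payload)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _mrc_header(nx: int, ny: int, nz: int, data: np.ndarray,
                pixel_size: float) -> bytes:
    hdr = bytearray(_HEADER_SIZE)
    struct.pack_into("<3i", hdr, 0, nx, ny, nz)
    struct.pack_into("<i", hdr, 12, _MODE_FLOAT32)
    struct.pack_into("<3i", hdr, 28, nx, ny, nz)              # mx, my, mz
    struct.pack_into("<3f", hdr, 40, nx * pixel_size,
                     ny * pixel_size, nz * pixel_size)        # cella
    struct.pack_into("<3f", hdr, 52, 90.0, 90.0, 90.0)        # cellb
    struct.pack_into("<3i", hdr, 64, 1, 2, 3)                 # mapc/mapr/maps
    struct.pack_into("<3f", hdr, 76, float(data.min()),
                     float(data.max()), float(data.mean()))
    struct.pack_into("<i", hdr, 88, 0)                        # ispg
    struct.pack_into("<i", hdr, 92, 0)                        # nsymbt
    hdr[208:212] = b"MAP "
    hdr[212:216] = bytes([0x44, 0x44, 0x00, 0x00])            # little endian
    struct.pack_into("<f", hdr, 216, float(data.std()))       # rms
    struct.pack_into("<i", hdr, 220, 0)                       # nlabl
    return bytes(hdr)


def write_mrc(path: Union[str, Path], data: np.ndarray,
              pixel_size: float = 1.0) -> None:
    """Write a 2-D image (single section) or 3-D stack as MRC mode 2."""
    arr = np.asarray(data, dtype=np.float32)
    if not np.all(np.isfinite(arr)):
        raise ValueError("cannot write non-finite data")
    if arr.ndim == 2:
        nz, (ny, nx) = 1, arr.shape
    elif arr.ndim == 3:
        nz, ny, nx = arr.shape
    else:
        raise FormatError("MRC writer accepts 2-D or 3-D arrays")
    hdr = _mrc_header(nx, ny, nz, arr, pixel_size)
    _atomic_write(path, hdr + arr.astype("<f4").tobytes())


def read_mrc(path: Union[str, Path]) -> tuple[np.ndarray, dict]:
    """Read an MRC file (mode 2 only); returns (data, header summary).

    Byte order is auto-detected from the mode/dimension words; extended
    headers are skipped, not parsed.
    """
    raw = Path(path).read_bytes()
    if len(raw) < _HEADER_SIZE:
        raise FormatError(f"{path}: file shorter than an MRC header")

    def fields(order: str):
        nx, ny, nz = struct.unpack_from(order + "3i", raw, 0)
        (mode,) = struct.unpack_from(order + "i", raw, 12)
        (nsymbt,) = struct.unpack_from(order + "i", raw, 92)
        return nx, ny, nz, mode, nsymbt

    order = "<"
    nx, ny, nz, mode, nsymbt = fields(order)
    plausible = (0 < nx < 100_000 and 0 < ny < 100_000 and 0 <= mode <= 16)
    if not plausible:
        order = ">"
        nx, ny, nz, mode, nsymbt = fields(order)
        if not (0 < nx < 100_000 and 0 < ny < 100_000 and 0 <= mode <= 16):
            raise FormatError(f"{path}: not a recognizable MRC header")
    if mode != _MODE_FLOAT32:
        raise FormatError(
            f"{path}: unsupported MRC mode {mode} (only mode 2 supported)")
    dmin, dmax, dmean = struct.unpack_from(order + "3f", raw, 76)
    cella = struct.unpack_from(order + "3f", raw, 40)
    start = _HEADER_SIZE + nsymbt
    count = nx * ny * nz
    data = np.frombuffer(raw, dtype=order + "f4", count=count, offset=start)
    data = data.reshape(nz, ny, nx).astype(np.float64)
    header = {"nx": nx, "ny": ny, "nz": nz, "mode": mode,
              "dmin": float(dmin), "dmax": float(dmax),
              "dmean": float(dmean),
              "pixel_size": float(cella[0] / nx) if nx else 1.0,
              "byte_order": order}
    return data, header


def write_rawtlt(path: Union[str, Path], angles: np.ndarray) -> None:
    text = "".join(f"{a:.2f}\n" for a in np.asarray(angles, dtype=float))
    _atomic_write(path, text.encode())


def read_rawtlt(path: Union[str, Path]) -> np.ndarray:
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()
             if ln.strip()]
    try:
        return np.array([float(ln) for ln in lines])
    except ValueError as exc:
        raise FormatError(f"{path}: bad tilt angle line: {exc}") from exc


def write_tilt_series(stack: ProjectionStack, mrc_path: Union[str, Path],
                      angles_path: Union[str, Path]) -> None:
    """Write a projection stack as MRC (one section per tilt) + .rawtlt."""
    data = stack.data
    if data.ndim == 2:  # 1-D projections -> sections of height 1
        data = data[:, None, :]
    write_mrc(mrc_path, data, stack.pixel_size)
    write_rawtlt(angles_path, stack.angles)


def read_tilt_series(mrc_path: Union[str, Path],
                     angles_path: Union[str, Path]) -> ProjectionStack:
    """Read projections (MRC stack) plus tilt angles (.rawtlt)."""
    data, header = read_mrc(mrc_path)
    angles = read_rawtlt(angles_path)
    if data.shape[0] != angles.size:
        raise FormatError(
            f"{data.shape[0]} sections in {mrc_path} but {angles.size} "
            f"angles in {angles_path}")
    if data.shape[1] == 1:
        data = data[:, 0, :]
    return ProjectionStack(data, angles, header["pixel_size"],
                           provenance=f"{mrc_path} (mode {header['mode']}, "
                                      f"{header['byte_order']}-endian)")


def write_image(path: Union[str, Path], values: np.ndarray,
                pixel_size: float = 1.0) -> None:
    """Write a 2-D grid as MRC (``.mrc``) or CSV (anything else)."""
    if str(path).endswith(".mrc"):
        write_mrc(path, values, pixel_size)
    else:
        buf = "\n".join(",".join(f"{v!r}" for v in row) for row in values)
        _atomic_write(path, (buf + "\n").encode())


def read_image(path: Union[str, Path]) -> np.ndarray:
    if str(path).endswith(".mrc"):
        data, _ = read_mrc(path)
        return data[0] if data.shape[0] == 1 else data
    return np.loadtxt(path, delimiter=",")
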