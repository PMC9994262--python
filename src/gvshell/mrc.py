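"""Minimal MRC2014 (mode 2, float32) image reader/writer.

Covers exactly what the projection tools need: single 2D/3D float maps with
a pixel size.  Header layout follows the MRC2014 standard; no extended
headers, no compressed variants.
"""

from __future__ import annotations

import struct

import numpy as np

__all__ = ["read_mrc", "write_mrc"]

_HEADER_SIZE = 1024
_MAP_ID = b"MAP "


def write_mrc(path, data: np.ndarray, pixel_size: float = 1.0) -> None:
    data = np.asarray(data, dtype=np.float32)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError("MRC data must be 2D or 3D")
    nz, ny, nx = data.shape
    header = bytearray(_HEADER_SIZE)
    struct.pack_into("<3i", header, 0, nx, ny, nz)
    struct.pack_into("<i", header, 12, 2)  # mode 2 = float32
    struct.pack_into("<3i", header, 28, nx, ny, nz)  # mx, my, mz
    struct.pack_into("<3f", header, 40, nx * pixel_size, ny * pixel_size,
                     nz * pixel_size)  # cell dimensions
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # axis order
    struct.pack_into("<3f", header, 76, float(data.min()), float(data.max()),
                     float(data.mean()))
    struct.pack_into("<i", header, 92, 0)  # ispg
    header[208:212] = _MAP_ID
    header[212:216] = b"\x44\x44\x00\x00"  # little-endian machine stamp
    struct.pack_into("<f", header, 216, float(data.std()))
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(data.tobytes())


def read_mrc(path) -> tuple[np.ndarray, float]:
    """Return ``(data, pixel_size)``; 2D maps are squeezed to 2D."""
    with open(path, "rb") as fh:
        header = fh.read(_HEADER_SIZE)
        nx, ny, nz = struct.unpack_from("<3i", header, 0)
        mode, = struct.unpack_from("<i", header, 12)
        if mode != 2:
            raise ValueError(f"only mode-2 (float32) MRC supported, got mode {mode}")
        xlen, = struct.unpack_from("<f", header, 40)
        mx, = struct.unpack_from("<i", header, 28)
        pixel = xlen / mx if mx else 1.0
        data = np.frombuffer(fh.read(nx * ny * nz * 4), dtype="<f4")
    data = data.reshape(nz, ny, nx)
    if nz == 1:
        data = data[0]
    return data.astype(np.float32), float(pixel)
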