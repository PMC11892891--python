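"""Minimal single-image CBF reader/writer with byte-offset payloads.

A small self-consistent dialect of the crystallographic binary file format:
a CIF text header with the documented subset of fields (dimensions, pixel
size, oscillation), then the standard MIME binary section whose payload is
encoded with this package's byte-offset codec.  The standard binary start
marker ``0x0C 0x1A 0x04 0xD5`` is used, so the payload framing matches what
CBF tooling expects; full CIF header parsing is out of scope.
"""

from __future__ import annotations

import hashlib
import re

import numpy as np

from .byteoffset import ByteOffsetBlob, decode_byte_offset, encode_byte_offset
from .core import Frame, default_sentinel, mask_to_sentinel, sentinel_to_mask

__all__ = ["write_frame_cbf", "read_frame_cbf"]

_BINARY_MARKER = b"\x0c\x1a\x04\xd5"
_BOUNDARY = b"--CIF-BINARY-FORMAT-SECTION--"


def write_frame_cbf(
    frame: Frame,
    path,
    pixel_size: float = 0.075,
    osc_start: float = 0.0,
    osc_width: float = 0.2,
    sentinel: int | None = None,
) -> None:
    dtype = np.uint32
    if sentinel is None:
        sentinel = default_sentinel(dtype)
    raw = mask_to_sentinel(frame, sentinel, dtype)
    blob = encode_byte_offset(raw.astype(np.int64).ravel(), dtype_tag=4)
    payload = blob.payload
    md5 = hashlib.md5(payload).hexdigest()
    rows, cols = frame.shape
    header = (
        "###CBF: VERSION 1.5\n"
        "# mxsqueeze minimal single-image CBF\n\n"
        "data_image_0\n\n"
        "_array_data.header_convention \"MXSQUEEZE_MINIMAL_1.0\"\n"
        "_array_data.header_contents\n"
        ";\n"
        f"# Pixel_size {pixel_size:.6f} mm x {pixel_size:.6f} mm\n"
        f"# Start_angle {osc_start:.4f} deg.\n"
        f"# Angle_increment {osc_width:.4f} deg.\n"
        f"# Sentinel {sentinel}\n"
        ";\n\n"
        "_array_data.data\n"
        ";\n"
    ).encode("ascii")
    mime = (
        _BOUNDARY + b"\n"
        b"Content-Type: application/octet-stream;\n"
        b'     conversions="x-CBF_BYTE_OFFSET"\n'
        b"Content-Transfer-Encoding: BINARY\n"
        + f"X-Binary-Size: {len(payload)}\n".encode()
        + b"X-Binary-ID: 1\n"
        + b'X-Binary-Element-Type: "signed 32-bit integer"\n'
        + b"X-Binary-Element-Byte-Order: LITTLE_ENDIAN\n"
        + f"Content-MD5: {md5}\n".encode()
        + f"X-Binary-Number-of-Elements: {rows * cols}\n".encode()
        + f"X-Binary-Size-Fastest-Dimension: {cols}\n".encode()
        + f"X-Binary-Size-Second-Dimension: {rows}\n".encode()
        + b"X-Binary-Size-Padding: 0\n\n"
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(mime)
        fh.write(_BINARY_MARKER)
        fh.write(payload)
        fh.write(b"\n" + _BOUNDARY + b"\n;\n")


def _field(headers: bytes, name: str, cast=int):
    m = re.search((name + r":\s*([^\r\n]+)").encode(), headers)
    if m is None:
        raise ValueError(f"CBF binary section missing {name}")
    return cast(m.group(1).decode().strip())


def read_frame_cbf(path, frame_index: int = 0) -> Frame:
    with open(path, "rb") as fh:
        data = fh.read()
    start = data.find(_BOUNDARY)
    if start < 0:
        raise ValueError("no CIF binary section found")
    marker = data.find(_BINARY_MARKER, start)
    if marker < 0:
        raise ValueError("binary start marker not found")
    headers = data[start:marker]
    if b"x-CBF_BYTE_OFFSET" not in headers:
        raise ValueError("unsupported CBF compression (only x-CBF_BYTE_OFFSET)")
    size = _field(headers, "X-Binary-Size")
    n_elements = _field(headers, "X-Binary-Number-of-Elements")
    cols = _field(headers, "X-Binary-Size-Fastest-Dimension")
    rows = _field(headers, "X-Binary-Size-Second-Dimension")
    if rows * cols != n_elements:
        raise ValueError("inconsistent CBF dimensions")
    payload = data[marker + 4 : marker + 4 + size]
    values = decode_byte_offset(ByteOffsetBlob(payload, n_elements, 4))
    plane = values.reshape(rows, cols)
    m = re.search(rb"# Sentinel (\d+)", data[:start])
    sentinel = int(m.group(1)) if m else default_sentinel(np.uint32)
    # decoded values are the signed view of the stored raster; undo for
    # sentinel comparison
    unsigned = plane.astype(np.int64) & 0xFFFFFFFF
    valid = unsigned != sentinel
    counts = np.where(valid, plane, 0).astype(np.int32)
    return Frame(counts, valid, frame_index)
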