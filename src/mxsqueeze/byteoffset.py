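"""CBF-style byte-offset lossless codec.

Successive pixel differences are stored in one signed byte, with escape
markers to 16-, 32- and 64-bit little-endian integers for larger deltas:

* delta in [-127, 127]          -> 1 signed byte
* else marker ``0x80``, then delta in [-32767, 32767] as int16 LE
* else marker ``0x8000`` (int16 LE), then delta as int32 LE if it fits
* else marker ``0x80000000`` (int32 LE), then delta as int64 LE

The initial "previous value" is 0, the raster is a single row-major stream
with no row restarts, and ratios are computed on payload bytes only (no
container overhead).  This is the lossless baseline against which the extra
compression ratio of every lossy pipeline is measured.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import FrameStack, mask_to_sentinel

__all__ = [
    "ByteOffsetBlob",
    "encode_byte_offset",
    "decode_byte_offset",
    "byte_offset_size",
    "TruncatedPayloadError",
]

_I16_MARKER = -32768
_I32_MARKER = -2147483648


class TruncatedPayloadError(ValueError):
    """Payload ended mid-value; reports the byte offset reached."""


@dataclass(frozen=True)
class ByteOffsetBlob:
    payload: bytes
    n_values: int
    dtype_tag: int  # original element width in bytes


def encode_byte_offset(values, dtype_tag: int = 4) -> ByteOffsetBlob:
    """Encode a 1-D signed integer sequence with the byte-offset dialect."""
    v = np.asarray(values).astype(np.int64).ravel()
    n = v.size
    if n == 0:
        return ByteOffsetBlob(b"", 0, dtype_tag)
    deltas = np.empty(n, dtype=np.int64)
    deltas[0] = v[0]
    np.subtract(v[1:], v[:-1], out=deltas[1:])

    w8 = (deltas >= -127) & (deltas <= 127)
    w16 = ~w8 & (deltas >= -32767) & (deltas <= 32767)
    w32 = ~(w8 | w16) & (deltas >= -2147483647) & (deltas <= 2147483647)
    w64 = ~(w8 | w16 | w32)

    sizes = np.ones(n, dtype=np.int64)
    sizes[w16] = 3
    sizes[w32] = 7
    sizes[w64] = 15
    starts = np.empty(n, dtype=np.int64)
    starts[0] = 0
    np.cumsum(sizes[:-1], out=starts[1:])
    out = np.zeros(int(sizes.sum()), dtype=np.uint8)

    out[starts[w8]] = deltas[w8].astype(np.int8).view(np.uint8)

    s = starts[w16]
    out[s] = 0x80
    b = deltas[w16].astype("<i2").view(np.uint8).reshape(-1, 2)
    for k in range(2):
        out[s + 1 + k] = b[:, k]

    s = starts[w32]
    out[s] = 0x80
    out[s + 2] = 0x80  # int16 LE marker 0x8000 = bytes 00 80
    b = deltas[w32].astype("<i4").view(np.uint8).reshape(-1, 4)
    for k in range(4):
        out[s + 3 + k] = b[:, k]

    s = starts[w64]
    out[s] = 0x80
    out[s + 2] = 0x80
    out[s + 6] = 0x80  # int32 LE marker 0x80000000 = bytes 00 00 00 80
    b = deltas[w64].astype("<i8").view(np.uint8).reshape(-1, 8)
    for k in range(8):
        out[s + 7 + k] = b[:, k]

    return ByteOffsetBlob(out.tobytes(), n, dtype_tag)


def decode_byte_offset(blob: ByteOffsetBlob) -> np.ndarray:
    """Exact inverse of :func:`encode_byte_offset` (int64 output)."""
    payload = blob.payload
    buf = np.frombuffer(payload, dtype=np.int8)
    chunks: list[np.ndarray] = []
    pos = 0
    remaining = blob.n_values
    end = len(payload)
    while remaining > 0:
        idx = payload.find(b"\x80", pos)
        if idx < 0:
            idx = end
        run = min(idx - pos, remaining)
        if run:
            chunks.append(buf[pos : pos + run].astype(np.int64))
            pos += run
            remaining -= run
            if remaining == 0:
                break
        if pos >= end:
            raise TruncatedPayloadError(
                f"payload ended at byte {pos} with {remaining} values missing"
            )
        # payload[pos] is the 0x80 escape marker
        if pos + 3 > end:
            raise TruncatedPayloadError(f"payload truncated mid-escape at byte {pos}")
        delta = int.from_bytes(payload[pos + 1 : pos + 3], "little", signed=True)
        width = 3
        if delta == _I16_MARKER:
            if pos + 7 > end:
                raise TruncatedPayloadError(f"payload truncated mid-escape at byte {pos}")
            delta = int.from_bytes(payload[pos + 3 : pos + 7], "little", signed=True)
            width = 7
            if delta == _I32_MARKER:
                if pos + 15 > end:
                    raise TruncatedPayloadError(
                        f"payload truncated mid-escape at byte {pos}"
                    )
                delta = int.from_bytes(payload[pos + 7 : pos + 15], "little", signed=True)
                width = 15
        chunks.append(np.array([delta], dtype=np.int64))
        pos += width
        remaining -= 1
    if not chunks:
        return np.empty(0, dtype=np.int64)
    deltas = np.concatenate(chunks)
    return np.cumsum(deltas)


def byte_offset_size(stack: FrameStack, sentinel: int | None = None, dtype=np.uint32) -> int:
    """Total byte-offset payload bytes for a stack (the ECR denominator base).

    Each frame is converted to its on-disk sentinel-substituted raster first,
    so the measured stream is the one a beamline would actually store.
    """
    total = 0
    for frame in stack:
        raw = mask_to_sentinel(frame, sentinel=sentinel, dtype=dtype)
        blob = encode_byte_offset(raw.astype(np.int64).ravel(), dtype_tag=raw.dtype.itemsize)
        total += len(blob.payload)
    return total


def raw_size(stack: FrameStack, dtype=np.uint32) -> int:
    """Uncompressed on-disk size in bytes at the stored dtype width."""
    itemsize = np.dtype(dtype).itemsize
    return sum(f.counts.size * itemsize for f in stack)
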