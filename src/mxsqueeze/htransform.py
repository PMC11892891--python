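"""Integer H-transform (Haar pyramid) codec with a quantization scale.

The forward transform recursively replaces each 2x2 block
``[[p00, p01], [p10, p11]]`` by four integer combinations

    h0 = p00 + p01 + p10 + p11          (block sum; feeds the next level)
    hx = (p10 + p11) - (p00 + p01)      (row difference)
    hy = (p01 + p11) - (p00 + p10)      (column difference)
    hc = p11 - p10 - p01 + p00          (cross term)

No divisions are performed, so the transform is exactly invertible in
integer arithmetic (each pixel is recovered as an exact multiple-of-4
combination of the four coefficients).  Lossy operation quantizes every
non-DC coefficient by an integer ``scale`` (round half away from zero); the
DC band is never quantized so the reconstruction keeps the total count of
the plane.  Scales 0 and 1 are lossless.

The entropy stage codes each bit-plane of the coefficient magnitudes,
most-significant first, with a breadth-first quadtree significance map,
followed by one sign bit per nonzero coefficient.  The bitstream dialect is
identified as ``hqt1``; it is not byte-compatible with the astronomy
Hcompress program, whose scale semantics it models.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

import numpy as np

__all__ = [
    "HTransformPlane",
    "HcompBlob",
    "h_forward",
    "h_inverse",
    "encode_hcomp",
    "decode_hcomp",
    "fill_invalid",
    "CodecError",
    "CODEC_VARIANT",
]

CODEC_VARIANT = "hqt1"
_MAGIC = b"MXH1"


class CodecError(ValueError):
    """Malformed or inconsistent H-transform bitstream."""


@dataclass
class HTransformPlane:
    coefficients: np.ndarray  # int64, padded square 2^n_levels
    n_levels: int
    original_shape: tuple[int, int]


@dataclass
class HcompBlob:
    scale: int
    payload: bytes
    n_levels: int
    original_shape: tuple[int, int]
    codec_variant_id: str = CODEC_VARIANT

    def to_bytes(self) -> bytes:
        head = struct.pack(
            "<4s4sIBII",
            _MAGIC,
            self.codec_variant_id.encode("ascii"),
            self.scale,
            self.n_levels,
            self.original_shape[0],
            self.original_shape[1],
        )
        return head + self.payload

    @classmethod
    def from_bytes(cls, data: bytes) -> "HcompBlob":
        if len(data) < 21 or data[:4] != _MAGIC:
            raise CodecError("not an hqt1 blob")
        magic, variant, scale, n_levels, rows, cols = struct.unpack("<4s4sIBII", data[:21])
        return cls(scale, data[21:], n_levels, (rows, cols), variant.decode("ascii"))


# ---------------------------------------------------------------------------
# Transform


def _padded_size(shape: tuple[int, int]) -> tuple[int, int]:
    n = 1
    levels = 0
    m = max(shape)
    while n < m:
        n *= 2
        levels += 1
    return n, levels


def h_forward(plane: np.ndarray) -> HTransformPlane:
    """Exact integer Haar pyramid of a 2-D signed integer plane.

    The plane is padded to the next power-of-two square by edge replication
    (sharp zero-padding edges would inject spurious high-frequency
    coefficients); the pad is cropped again on inversion.
    """
    plane = np.asarray(plane)
    if plane.ndim != 2 or plane.size == 0:
        raise ValueError("h_forward expects a non-empty 2-D plane")
    shape = plane.shape
    size, levels = _padded_size(shape)
    a = np.empty((size, size), dtype=np.int64)
    a[: shape[0], : shape[1]] = plane
    if shape[1] < size:
        a[: shape[0], shape[1] :] = a[: shape[0], shape[1] - 1 : shape[1]]
    if shape[0] < size:
        a[shape[0] :, :] = a[shape[0] - 1 : shape[0], :]

    s = size
    while s > 1:
        sub = a[:s, :s]
        p00 = sub[0::2, 0::2].copy()
        p01 = sub[0::2, 1::2].copy()
        p10 = sub[1::2, 0::2].copy()
        p11 = sub[1::2, 1::2].copy()
        h = s // 2
        a[:h, :h] = p00 + p01 + p10 + p11
        a[:h, h:s] = (p01 + p11) - (p00 + p10)
        a[h:s, :h] = (p10 + p11) - (p00 + p01)
        a[h:s, h:s] = p11 - p10 - p01 + p00
        s = h
    return HTransformPlane(a, levels, shape)


def h_inverse(coeffs: HTransformPlane) -> np.ndarray:
    """Invert :func:`h_forward`; exact on unquantized coefficients."""
    a = np.asarray(coeffs.coefficients, dtype=np.int64).copy()
    size = 1 << coeffs.n_levels
    if a.shape != (size, size):
        raise CodecError(
            f"coefficient plane {a.shape} inconsistent with n_levels={coeffs.n_levels}"
        )
    r, c = coeffs.original_shape
    if r > size or c > size:
        raise CodecError("original_shape exceeds padded size")
    s = 1
    while s < size:
        d = 2 * s
        h0 = a[:s, :s].copy()
        hy = a[:s, s:d].copy()
        hx = a[s:d, :s].copy()
        hc = a[s:d, s:d].copy()
        sub = a[:d, :d]
        # each 4*pixel combination is exact for unquantized coefficients;
        # for quantized input this is the reconstruction the dequantized
        # coefficients imply, with floor-of-quarter rounding
        sub[0::2, 0::2] = (h0 - hx - hy + hc) >> 2
        sub[0::2, 1::2] = (h0 - hx + hy - hc) >> 2
        sub[1::2, 0::2] = (h0 + hx - hy - hc) >> 2
        sub[1::2, 1::2] = (h0 + hx + hy + hc) >> 2
        s = d
    return a[:r, :c]


# ---------------------------------------------------------------------------
# Quantization


def _quantize(coeffs: np.ndarray, scale: int) -> np.ndarray:
    """Round half away from zero on all but the DC coefficient."""
    if scale < 2:
        return coeffs.copy()
    mag = np.abs(coeffs)
    q = np.sign(coeffs) * ((2 * mag + scale) // (2 * scale))
    q[0, 0] = coeffs[0, 0]  # DC never quantized: total count preserved
    return q


def _dequantize(q: np.ndarray, scale: int) -> np.ndarray:
    if scale < 2:
        return q.copy()
    c = q * np.int64(scale)
    c[0, 0] = q[0, 0]
    return c


# ---------------------------------------------------------------------------
# Quadtree bit-plane entropy coder

_CHILD_R = np.array([0, 0, 1, 1])
_CHILD_C = np.array([0, 1, 0, 1])


def _or_pyramid(bits: np.ndarray) -> list[np.ndarray]:
    levels = [bits]
    p = bits
    while p.shape[0] > 1:
        p = p.reshape(p.shape[0] // 2, 2, p.shape[1] // 2, 2).any(axis=(1, 3))
        levels.append(p)
    return levels


def _encode_plane_bits(mag: np.ndarray, n_bitplanes: int) -> list[np.ndarray]:
    """Per-bit-plane quadtree significance streams, MSB first."""
    chunks: list[np.ndarray] = []
    k = int(np.log2(mag.shape[0])) if mag.shape[0] > 1 else 0
    for b in range(n_bitplanes - 1, -1, -1):
        bits = ((mag >> b) & 1).astype(bool)
        pyr = _or_pyramid(bits)
        active_r = np.zeros(1, dtype=np.int64)
        active_c = np.zeros(1, dtype=np.int64)
        for level in range(k, -1, -1):
            vals = pyr[level][active_r, active_c]
            chunks.append(vals.astype(np.uint8))
            if level > 0:
                sig = np.nonzero(vals)[0]
                r = active_r[sig]
                c = active_c[sig]
                active_r = (2 * r[:, None] + _CHILD_R).ravel()
                active_c = (2 * c[:, None] + _CHILD_C).ravel()
                if active_r.size == 0:
                    break
    return chunks


class _BitReader:
    def __init__(self, data: bytes):
        self.bits = np.unpackbits(np.frombuffer(data, dtype=np.uint8))
        self.pos = 0

    def take(self, n: int) -> np.ndarray:
        if self.pos + n > self.bits.size:
            raise CodecError("bitstream exhausted")
        out = self.bits[self.pos : self.pos + n]
        self.pos += n
        return out


def _decode_plane_bits(reader: _BitReader, size: int, n_bitplanes: int) -> np.ndarray:
    mag = np.zeros((size, size), dtype=np.int64)
    k = int(np.log2(size)) if size > 1 else 0
    for b in range(n_bitplanes - 1, -1, -1):
        active_r = np.zeros(1, dtype=np.int64)
        active_c = np.zeros(1, dtype=np.int64)
        for level in range(k, -1, -1):
            vals = reader.take(active_r.size).astype(bool)
            if level == 0:
                mag[active_r[vals], active_c[vals]] |= np.int64(1) << b
            else:
                sig = np.nonzero(vals)[0]
                r = active_r[sig]
                c = active_c[sig]
                active_r = (2 * r[:, None] + _CHILD_R).ravel()
                active_c = (2 * c[:, None] + _CHILD_C).ravel()
                if active_r.size == 0:
                    break
    return mag


def encode_hcomp(plane: np.ndarray, scale: int) -> HcompBlob:
    """Transform, quantize by ``scale`` and entropy-code a count plane."""
    if scale < 0:
        raise ValueError("scale must be >= 0")
    t = h_forward(plane)
    q = _quantize(t.coefficients, scale)
    mag = np.abs(q)
    n_bitplanes = int(mag.max()).bit_length()
    chunks = _encode_plane_bits(mag, n_bitplanes)
    nonzero = q.ravel() != 0
    signs = (q.ravel()[nonzero] < 0).astype(np.uint8)
    chunks.append(signs)
    stream = np.concatenate(chunks) if chunks else np.empty(0, dtype=np.uint8)
    payload = struct.pack("<B", n_bitplanes) + np.packbits(stream).tobytes()
    return HcompBlob(scale, payload, t.n_levels, t.original_shape)


def decode_hcomp(blob: HcompBlob) -> np.ndarray:
    """Dequantize, inverse-transform and crop a compressed plane."""
    if blob.codec_variant_id != CODEC_VARIANT:
        raise CodecError(f"unknown codec variant {blob.codec_variant_id!r}")
    if len(blob.payload) < 1:
        raise CodecError("empty payload")
    n_bitplanes = blob.payload[0]
    size = 1 << blob.n_levels
    reader = _BitReader(blob.payload[1:])
    mag = _decode_plane_bits(reader, size, n_bitplanes)
    nz_r, nz_c = np.nonzero(mag)
    signs = reader.take(nz_r.size).astype(bool)
    q = mag
    q[nz_r[signs], nz_c[signs]] *= -1
    coeffs = _dequantize(q, blob.scale)
    out = h_inverse(HTransformPlane(coeffs, blob.n_levels, blob.original_shape))
    return out


# ---------------------------------------------------------------------------
# Mask filling


def fill_invalid(counts: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Replace invalid pixels by the median of valid 5x5 neighbours.

    Gap edges otherwise dominate the wavelet budget.  Pixels deep inside a
    gap, with no valid neighbour in the window, fall back to the global
    median of the valid pixels.  The validity plane itself is carried
    losslessly elsewhere, so no information is invented at invalid pixels.
    """
    counts = np.asarray(counts)
    valid = np.asarray(valid, dtype=bool)
    if valid.all():
        return counts.astype(np.int64)
    work = counts.astype(np.float64)
    work[~valid] = np.nan
    padded = np.pad(work, 2, mode="constant", constant_values=np.nan)
    inv_r, inv_c = np.nonzero(~valid)
    windows = np.empty((inv_r.size, 25), dtype=np.float64)
    idx = 0
    for dr in range(5):
        for dc in range(5):
            windows[:, idx] = padded[inv_r + dr, inv_c + dc]
            idx += 1
    import warnings as _warnings

    with _warnings.catch_warnings():
        # all-NaN windows are expected deep inside gaps; handled below
        _warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(windows, axis=1)
    global_med = float(np.median(counts[valid])) if valid.any() else 0.0
    med = np.where(np.isnan(med), global_med, med)
    out = counts.astype(np.int64).copy()
    out[inv_r, inv_c] = np.round(med).astype(np.int64)
    return out
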