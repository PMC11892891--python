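"""Reduction operators and pipeline composition.

Pixel binning (BINn) sums n x n blocks within a frame; frame summing (SUMm)
sums m consecutive frames pixel-by-pixel, coarsening the rotation slice
m-fold.  Both conserve total counts, commute exactly with each other, and
together reduce the stored sample count by n^2 * m.  Detector and scan
metadata (pixel size, pixel counts, beam centre, gap rectangles, oscillation
width, count time) are updated alongside, and every transformation is
recorded in the compressed container header.

Non-divisible remainders (trailing rows/columns under BIN, trailing frames
under SUM) are dropped, not padded — padding would bias the sums — and the
drop is recorded.
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import dataclass

import numpy as np

from . import htransform, wavelet
from .byteoffset import ByteOffsetBlob, decode_byte_offset, encode_byte_offset
from .core import (
    Bin,
    ByteOffset,
    CompressedStack,
    DetectorGeometry,
    Frame,
    FrameStack,
    Hcomp,
    PipelineSpec,
    ScanMetadata,
    Sum,
    Wavelet,
    mask_to_sentinel,
)

__all__ = [
    "Grey16Image",
    "bin_pixels",
    "bin_metadata",
    "sum_frames",
    "to_grey16",
    "compress_pipeline",
    "decompress_pipeline",
    "reduce_stack",
    "FramesDroppedWarning",
]


class FramesDroppedWarning(UserWarning):
    """Remainder frames (or rows/columns) were dropped by a reduction."""


@dataclass
class Grey16Image:
    """16-bit greyscale conversion of a frame, for external wavelet codecs."""

    plane: np.ndarray  # uint16
    clip_count: int
    mask_payload: np.ndarray  # bool plane carried alongside


# ---------------------------------------------------------------------------
# Reduction operators


def bin_pixels(frame: Frame, n: int) -> Frame:
    """Sum n x n pixel blocks; a superpixel is invalid iff any source is."""
    if n < 2:
        raise ValueError("bin factor must be >= 2")
    rows, cols = frame.shape
    if n > rows or n > cols:
        raise ValueError(f"bin factor {n} exceeds frame dimensions {frame.shape}")
    out_r, out_c = rows // n, cols // n
    counts = frame.counts[: out_r * n, : out_c * n].astype(np.int64)
    valid = frame.valid[: out_r * n, : out_c * n]
    binned = counts.reshape(out_r, n, out_c, n).sum(axis=(1, 3))
    all_valid = valid.reshape(out_r, n, out_c, n).all(axis=(1, 3))
    if binned.max(initial=0) > np.iinfo(np.int32).max:
        raise OverflowError("binned counts exceed 31-bit dynamic range")
    binned = np.where(all_valid, binned, 0)
    return Frame(binned.astype(np.int32), all_valid, frame.frame_index)


def bin_metadata(
    geometry: DetectorGeometry, scan: ScanMetadata, n: int
) -> tuple[DetectorGeometry, ScanMetadata]:
    """Geometry updates for BINn: pixel size x n, pixel counts and beam
    centre / n, gap rectangles mapped to any-overlap superpixel intervals.
    The scan is unchanged (binning acts within a frame)."""
    if n < 2:
        raise ValueError("bin factor must be >= 2")
    out_r, out_c = geometry.n_rows // n, geometry.n_cols // n
    gaps = []
    for r0, r1, c0, c1 in geometry.gap_regions:
        g = (r0 // n, -(-r1 // n), c0 // n, -(-c1 // n))  # any overlap -> included
        g = (min(g[0], out_r), min(g[1], out_r), min(g[2], out_c), min(g[3], out_c))
        if g[0] < g[1] and g[2] < g[3]:
            gaps.append(g)
    geo = DetectorGeometry(
        n_rows=out_r,
        n_cols=out_c,
        pixel_size=geometry.pixel_size * n,
        beam_center_row=geometry.beam_center_row / n,
        beam_center_col=geometry.beam_center_col / n,
        detector_distance=geometry.detector_distance,
        wavelength=geometry.wavelength,
        gap_regions=tuple(gaps),
    )
    return geo, scan


def sum_frames(stack: FrameStack, m: int) -> FrameStack:
    """Pixel-wise sum of m consecutive frames; oscillation width and count
    time scale by m, remainder frames are dropped with a warning."""
    if m < 2:
        raise ValueError("sum factor must be >= 2")
    n = len(stack)
    if m > n:
        raise ValueError(f"sum factor {m} exceeds stack length {n}")
    n_out = n // m
    dropped = n - n_out * m
    if dropped:
        warnings.warn(
            f"sum_frames({m}) dropped {dropped} trailing frame(s)",
            FramesDroppedWarning,
            stacklevel=2,
        )
    frames = []
    for j in range(n_out):
        acc = np.zeros(stack.shape, dtype=np.int64)
        valid = np.ones(stack.shape, dtype=bool)
        for i in range(j * m, (j + 1) * m):
            acc += stack[i].counts.astype(np.int64)
            valid &= stack[i].valid
        if acc.max(initial=0) > np.iinfo(np.int32).max:
            raise OverflowError("summed counts exceed 31-bit dynamic range")
        acc = np.where(valid, acc, 0)
        frames.append(Frame(acc.astype(np.int32), valid, j))
    scan = ScanMetadata(
        osc_start=stack.scan.osc_start,
        osc_width=stack.scan.osc_width * m,
        n_frames=n_out,
        count_time=stack.scan.count_time * m,
    )
    return FrameStack(frames, stack.geometry, scan)


def to_grey16(frame: Frame) -> Grey16Image:
    """Clip counts to [0, 65535] for the external wavelet codec path.

    Invalid pixels are written as 0; the mask travels separately."""
    counts = frame.counts
    clipped = np.clip(counts, 0, 65535)
    clip_count = int((counts > 65535).sum())
    plane = np.where(frame.valid, clipped, 0).astype(np.uint16)
    return Grey16Image(plane, clip_count, frame.valid.copy())


def reduce_stack(stack: FrameStack, bin_n: int | None, sum_m: int | None) -> FrameStack:
    """Apply BIN then SUM (the two commute exactly; BIN first is cheaper
    once frames shrink)."""
    out = stack
    if bin_n:
        geo, scan = bin_metadata(out.geometry, out.scan, bin_n)
        frames = [bin_pixels(f, bin_n) for f in out]
        out = FrameStack(frames, geo, scan)
    if sum_m:
        out = sum_frames(out, sum_m)
    return out


# ---------------------------------------------------------------------------
# Pipeline application

_RAW_VARIANT = "raw-i4"
_BO_VARIANT = "cbf-bo"


def _geometry_dict(g: DetectorGeometry) -> dict:
    return {
        "n_rows": g.n_rows,
        "n_cols": g.n_cols,
        "pixel_size": g.pixel_size,
        "beam_center_row": g.beam_center_row,
        "beam_center_col": g.beam_center_col,
        "detector_distance": g.detector_distance,
        "wavelength": g.wavelength,
        "gap_regions": [list(r) for r in g.gap_regions],
    }


def _geometry_from_dict(d: dict) -> DetectorGeometry:
    return DetectorGeometry(
        n_rows=d["n_rows"],
        n_cols=d["n_cols"],
        pixel_size=d["pixel_size"],
        beam_center_row=d["beam_center_row"],
        beam_center_col=d["beam_center_col"],
        detector_distance=d["detector_distance"],
        wavelength=d["wavelength"],
        gap_regions=tuple(tuple(r) for r in d["gap_regions"]),
    )


def _scan_dict(s: ScanMetadata) -> dict:
    return {
        "osc_start": s.osc_start,
        "osc_width": s.osc_width,
        "n_frames": s.n_frames,
        "count_time": s.count_time,
    }


def _scan_from_dict(d: dict) -> ScanMetadata:
    return ScanMetadata(**d)


def pack_mask(valid: np.ndarray) -> bytes:
    return zlib.compress(np.packbits(valid.astype(np.uint8)).tobytes(), 9)


def unpack_mask(payload: bytes, shape: tuple[int, int]) -> np.ndarray:
    bits = np.unpackbits(np.frombuffer(zlib.decompress(payload), dtype=np.uint8))
    return bits[: shape[0] * shape[1]].reshape(shape).astype(bool)


def compress_pipeline(stack: FrameStack, spec: PipelineSpec) -> CompressedStack:
    """Apply a pipeline: BIN/SUM restructure the stack, then the terminal
    codec (if any) encodes each frame.  All metadata transformations are
    recorded in the header so decompression is self-contained."""
    bin_n = spec.bin_factor
    sum_m = spec.sum_factor
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", FramesDroppedWarning)
        reduced = reduce_stack(stack, bin_n, sum_m)
    drop_notes = [str(w.message) for w in caught]
    if bin_n:
        rr = stack.geometry.n_rows % bin_n
        cc = stack.geometry.n_cols % bin_n
        if rr or cc:
            drop_notes.append(f"bin_pixels({bin_n}) dropped {rr} row(s), {cc} col(s)")

    valid = (
        reduced[0].valid if len(reduced) else np.ones(reduced.shape, dtype=bool)
    )
    codec = spec.codec
    blobs: list[bytes] = []
    clip_total = 0
    if codec is None:
        variant = _RAW_VARIANT
        for f in reduced:
            blobs.append(f.counts.astype("<i4").tobytes())
    elif isinstance(codec, ByteOffset):
        variant = _BO_VARIANT
        for f in reduced:
            blob = encode_byte_offset(f.counts.ravel())
            blobs.append(blob.payload)
    elif isinstance(codec, Hcomp):
        variant = htransform.CODEC_VARIANT
        for f in reduced:
            filled = htransform.fill_invalid(f.counts, f.valid)
            blobs.append(htransform.encode_hcomp(filled, codec.scale).to_bytes())
    elif isinstance(codec, Wavelet):
        if not wavelet.jpeg2000_available():  # pragma: no cover - env has OpenJPEG
            raise wavelet.WaveletCodecUnavailable(
                "the WAVELET stage needs an external JPEG-2000 codec; install "
                "Pillow with OpenJPEG support to enable it"
            )
        variant = wavelet.J2K_VARIANT
        for f in reduced:
            # invalid pixels keep their smooth fill inside the codec input
            # (zeros would put sharp edges in the wavelet budget); the mask
            # restores them after decode
            filled = htransform.fill_invalid(f.counts, f.valid)
            clip_total += int((filled > 65535).sum())
            plane = np.clip(filled, 0, 65535).astype(np.uint16)
            blobs.append(wavelet.encode_j2k(plane, codec.target_ratio))
    else:  # pragma: no cover
        raise ValueError(f"unsupported codec stage {codec}")

    header = {
        "format": "mxz-1",
        "pipeline": str(spec),
        "codec_variant_id": variant,
        "original_geometry": _geometry_dict(stack.geometry),
        "original_scan": _scan_dict(stack.scan),
        "geometry": _geometry_dict(reduced.geometry),
        "scan": _scan_dict(reduced.scan),
        "shape": list(reduced.shape),
        "dtype": "int32",
        "n_frames": len(reduced),
        "drops": drop_notes,
        "clip_count": clip_total,
    }
    return CompressedStack(
        header=header,
        mask_payload=pack_mask(valid),
        blobs=blobs,
        codec_variant_id=variant,
    )


def decompress_pipeline(cstack: CompressedStack) -> FrameStack:
    """Decode a compressed stack at its reduced geometry (BIN/SUM are not
    inverted).  Lossy reconstructions are clipped at zero so valid pixels
    never go negative."""
    header = cstack.header
    shape = tuple(header["shape"])
    geometry = _geometry_from_dict(header["geometry"])
    scan = _scan_from_dict(header["scan"])
    valid = unpack_mask(cstack.mask_payload, shape)
    variant = cstack.codec_variant_id
    frames = []
    lossless = variant in (_RAW_VARIANT, _BO_VARIANT)
    for i, blob in enumerate(cstack.blobs):
        if variant == _RAW_VARIANT:
            counts = np.frombuffer(blob, dtype="<i4").reshape(shape).astype(np.int32)
        elif variant == _BO_VARIANT:
            values = decode_byte_offset(
                ByteOffsetBlob(blob, shape[0] * shape[1], 4)
            )
            counts = values.reshape(shape).astype(np.int32)
        elif variant == htransform.CODEC_VARIANT:
            counts = htransform.decode_hcomp(htransform.HcompBlob.from_bytes(blob))
            counts = np.clip(counts, 0, np.iinfo(np.int32).max).astype(np.int32)
        elif variant == wavelet.J2K_VARIANT:
            counts = wavelet.decode_j2k(blob).astype(np.int32)
        else:
            raise ValueError(f"unknown codec_variant_id {variant!r}")
        counts = np.where(valid, counts, 0) if not lossless else counts
        frames.append(Frame(counts.astype(np.int32), valid.copy(), i))
    return FrameStack(frames, geometry, scan)
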