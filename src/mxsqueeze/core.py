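"""Domain types shared across the package.

The in-memory model keeps detector gaps and defective pixels as an explicit
boolean validity plane; saturation-style sentinel values exist only at I/O
boundaries.  Conversion between the two representations lives here so that
codecs and metrics never see a sentinel.

Conventions: 0-based row-major pixel coordinates; intervals are half-open
``[start, stop)``; the beam centre is stored in (fractional) pixel units so
that binning updates are pure divisions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence, Union

import numpy as np

__all__ = [
    "DetectorGeometry",
    "ScanMetadata",
    "Frame",
    "FrameStack",
    "Bin",
    "Sum",
    "Hcomp",
    "Wavelet",
    "ByteOffset",
    "PipelineSpec",
    "CompressedStack",
    "validate_stack",
    "sentinel_to_mask",
    "mask_to_sentinel",
    "default_sentinel",
    "SentinelCollisionWarning",
]


class SentinelCollisionWarning(UserWarning):
    """A sentinel value small enough to collide with plausible photon counts."""


@dataclass(frozen=True)
class DetectorGeometry:
    """Flat single-panel detector description.

    ``gap_regions`` is a sequence of ``(row0, row1, col0, col1)`` half-open
    rectangles in pixel coordinates marking inter-module gaps.
    """

    n_rows: int
    n_cols: int
    pixel_size: float  # mm, square pixels
    beam_center_row: float  # pixels, 0-based, fractional allowed
    beam_center_col: float
    detector_distance: float  # mm
    wavelength: float  # Angstrom
    gap_regions: tuple = ()

    def __post_init__(self):
        if self.n_rows < 2 or self.n_cols < 2:
            raise ValueError("detector must be at least 2x2 pixels")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        gaps = tuple(tuple(int(v) for v in g) for g in self.gap_regions)
        for r0, r1, c0, c1 in gaps:
            if not (0 <= r0 <= r1 <= self.n_rows and 0 <= c0 <= c1 <= self.n_cols):
                raise ValueError(f"gap rectangle {(r0, r1, c0, c1)} outside frame bounds")
        object.__setattr__(self, "gap_regions", gaps)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def valid_plane(self) -> np.ndarray:
        """Boolean plane that is False inside every gap rectangle."""
        valid = np.ones(self.shape, dtype=bool)
        for r0, r1, c0, c1 in self.gap_regions:
            valid[r0:r1, c0:c1] = False
        return valid


@dataclass(frozen=True)
class ScanMetadata:
    """Rotation-scan bookkeeping for a contiguous series of frames."""

    osc_start: float  # degrees
    osc_width: float  # degrees per frame
    n_frames: int
    count_time: float = 0.0  # seconds per frame

    def __post_init__(self):
        if self.osc_width <= 0:
            raise ValueError("osc_width must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")

    @property
    def total_rotation(self) -> float:
        return self.n_frames * self.osc_width

    def phi_range(self, i: int) -> tuple[float, float]:
        """Half-open rotation interval covered by frame ``i``."""
        lo = self.osc_start + i * self.osc_width
        return (lo, lo + self.osc_width)


@dataclass
class Frame:
    """One detector exposure: photon counts plus a validity plane."""

    counts: np.ndarray  # int32, 2-D
    valid: np.ndarray  # bool, 2-D, False = gap/defective
    frame_index: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int32)
        self.valid = np.asarray(self.valid, dtype=bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def copy(self) -> "Frame":
        return Frame(self.counts.copy(), self.valid.copy(), self.frame_index)


@dataclass
class FrameStack:
    """Ordered contiguous rotation series sharing one geometry and scan."""

    frames: list
    geometry: DetectorGeometry
    scan: ScanMetadata

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)

    def __getitem__(self, i: int) -> Frame:
        return self.frames[i]

    @property
    def shape(self) -> tuple[int, int]:
        return self.geometry.shape

    def counts_array(self) -> np.ndarray:
        """(n_frames, rows, cols) int32 view of all count planes."""
        return np.stack([f.counts for f in self.frames])


# ---------------------------------------------------------------------------
# Pipeline stage descriptors


@dataclass(frozen=True)
class Bin:
    n: int

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("bin factor must be >= 2")

    def __str__(self):
        return f"bin{self.n}"


@dataclass(frozen=True)
class Sum:
    m: int

    def __post_init__(self):
        if self.m < 2:
            raise ValueError("sum factor must be >= 2")

    def __str__(self):
        return f"sum{self.m}"


@dataclass(frozen=True)
class Hcomp:
    scale: int

    def __post_init__(self):
        if self.scale < 0:
            raise ValueError("hcomp scale must be >= 0")

    def __str__(self):
        return f"hcomp:{self.scale}"


@dataclass(frozen=True)
class Wavelet:
    target_ratio: float

    def __post_init__(self):
        if self.target_ratio <= 1:
            raise ValueError("wavelet target ratio must exceed 1")

    def __str__(self):
        r = self.target_ratio
        return f"j2k:{int(r) if float(r).is_integer() else r}"


@dataclass(frozen=True)
class ByteOffset:
    def __str__(self):
        return "byteoffset"


Stage = Union[Bin, Sum, Hcomp, Wavelet, ByteOffset]
_CODEC_STAGES = (Hcomp, Wavelet, ByteOffset)


@dataclass(frozen=True)
class PipelineSpec:
    """Ordered compression recipe: optional BIN/SUM reduction, then at most
    one terminal codec stage (HCOMP, WAVELET or BYTEOFFSET)."""

    stages: tuple

    def __post_init__(self):
        stages = tuple(self.stages)
        object.__setattr__(self, "stages", stages)
        n_bin = sum(isinstance(s, Bin) for s in stages)
        n_sum = sum(isinstance(s, Sum) for s in stages)
        if n_bin > 1 or n_sum > 1:
            raise ValueError("at most one BIN and one SUM stage allowed")
        codec_idx = [i for i, s in enumerate(stages) if isinstance(s, _CODEC_STAGES)]
        if len(codec_idx) > 1:
            raise ValueError("at most one codec stage allowed")
        if codec_idx and codec_idx[0] != len(stages) - 1:
            raise ValueError("codec stage must be terminal (after BIN/SUM)")

    @property
    def bin_factor(self) -> int | None:
        for s in self.stages:
            if isinstance(s, Bin):
                return s.n
        return None

    @property
    def sum_factor(self) -> int | None:
        for s in self.stages:
            if isinstance(s, Sum):
                return s.m
        return None

    @property
    def codec(self) -> Stage | None:
        for s in self.stages:
            if isinstance(s, _CODEC_STAGES):
                return s
        return None

    def __str__(self):
        return ",".join(str(s) for s in self.stages)

    @classmethod
    def parse(cls, text: str) -> "PipelineSpec":
        """Parse the stage grammar ``bin<n>,sum<m>,hcomp:<scale>,j2k:<ratio>,byteoffset``."""
        stages: list[Stage] = []
        for token in text.split(","):
            token = token.strip().lower()
            if not token:
                continue
            if token.startswith("bin"):
                stages.append(Bin(int(token[3:])))
            elif token.startswith("sum"):
                stages.append(Sum(int(token[3:])))
            elif token.startswith("hcomp:"):
                stages.append(Hcomp(int(token[6:])))
            elif token.startswith("j2k:"):
                stages.append(Wavelet(float(token[4:])))
            elif token == "byteoffset":
                stages.append(ByteOffset())
            else:
                raise ValueError(
                    f"unknown pipeline stage {token!r}; grammar: "
                    "bin<n>, sum<m>, hcomp:<scale>, j2k:<ratio>, byteoffset"
                )
        return cls(tuple(stages))


@dataclass
class CompressedStack:
    """Self-describing compressed rotation series.

    ``header`` records the pipeline, the original and the post-reduction
    geometry/scan, drop/clip bookkeeping and the codec dialect so that
    decompression needs no outside information.  ``mask_payload`` carries the
    validity plane losslessly; ``blobs`` holds one codec payload per frame.
    """

    header: dict
    mask_payload: bytes
    blobs: list
    codec_variant_id: str


# ---------------------------------------------------------------------------
# Validation


def validate_stack(stack: FrameStack) -> list[str]:
    """Check every stack invariant; returns a list of violation strings.

    Never raises: an empty list means the stack is well formed.
    """
    violations: list[str] = []
    try:
        shape = stack.geometry.shape
        if len(stack.frames) != stack.scan.n_frames:
            violations.append(
                f"stack has {len(stack.frames)} frames but scan.n_frames={stack.scan.n_frames}"
            )
        ref_valid = None
        for pos, frame in enumerate(stack.frames):
            if frame.counts.shape != shape:
                violations.append(
                    f"frame {pos}: counts shape {frame.counts.shape} != geometry {shape}"
                )
                continue
            if frame.valid.shape != frame.counts.shape:
                violations.append(
                    f"frame {pos}: valid shape {frame.valid.shape} != counts shape"
                )
                continue
            if frame.frame_index != pos:
                violations.append(
                    f"frame {pos}: frame_index {frame.frame_index} not strictly increasing from 0"
                )
            if ref_valid is None:
                ref_valid = frame.valid
            elif not np.array_equal(frame.valid, ref_valid):
                violations.append(f"frame {pos}: valid plane differs from frame 0")
            neg = frame.counts[frame.valid] < 0
            if neg.any():
                violations.append(
                    f"frame {pos}: {int(neg.sum())} negative counts at valid pixels"
                )
    except Exception as exc:  # pragma: no cover - validation must not raise
        violations.append(f"validation error: {exc!r}")
    return violations


# ---------------------------------------------------------------------------
# Sentinel <-> mask conversion (I/O boundary only)


def default_sentinel(dtype) -> int:
    """All-ones value of the stored dtype (e.g. 0xFFFFFFFF for uint32)."""
    return int(np.iinfo(np.dtype(dtype)).max)


def sentinel_to_mask(raw_plane: np.ndarray, sentinel: int, frame_index: int = 0) -> Frame:
    """Convert an on-disk plane whose gaps carry ``sentinel`` to a Frame.

    Invalid pixels get counts 0.  A sentinel below 2**16 collides with
    plausible photon counts; that is recorded as a warning, not an error.
    """
    raw = np.asarray(raw_plane)
    if sentinel < 2**16:
        warnings.warn(
            f"sentinel {sentinel} < 2^16 may collide with real photon counts",
            SentinelCollisionWarning,
            stacklevel=2,
        )
    valid = raw.astype(np.int64) != sentinel
    counts = np.where(valid, raw, 0).astype(np.int32)
    return Frame(counts=counts, valid=valid, frame_index=frame_index)


def mask_to_sentinel(frame: Frame, sentinel: int | None = None, dtype=np.uint32) -> np.ndarray:
    """Inverse of :func:`sentinel_to_mask`: invalid pixels become ``sentinel``.

    Raises if a valid pixel already carries the sentinel value (the encoding
    would be ambiguous and the round trip would silently lose the pixel).
    """
    dtype = np.dtype(dtype)
    if sentinel is None:
        sentinel = default_sentinel(dtype)
    counts = frame.counts.astype(np.int64)
    if np.any(counts[frame.valid] == sentinel):
        raise ValueError(f"valid pixel equals sentinel {sentinel}: ambiguous encoding")
    out = np.where(frame.valid, counts, sentinel)
    return out.astype(dtype)
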