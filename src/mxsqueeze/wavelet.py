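"""Adapter to an external JPEG-2000 (Daubechies wavelet) codec.

The wavelet stage is a contract, not an implementation: frames go through
the 16-bit greyscale path and an external codec addressed by a target
compression ratio.  Pillow's OpenJPEG binding fulfils the contract when it
is present; when it is not, requesting the stage raises an error that says
how to enable it — never a silent fallback.
"""

from __future__ import annotations

import io

import numpy as np

__all__ = ["WaveletCodecUnavailable", "jpeg2000_available", "encode_j2k", "decode_j2k", "J2K_VARIANT"]

J2K_VARIANT = "pil-j2k"


class WaveletCodecUnavailable(RuntimeError):
    pass


def _require_pillow():
    try:
        from PIL import Image, features
    except ImportError as exc:  # pragma: no cover
        raise WaveletCodecUnavailable(
            "the WAVELET stage needs an external JPEG-2000 codec; install "
            "Pillow built against OpenJPEG (pip install pillow) to enable it"
        ) from exc
    if not features.check("jpg_2000"):  # pragma: no cover
        raise WaveletCodecUnavailable(
            "Pillow is installed without OpenJPEG support; rebuild Pillow "
            "with OpenJPEG to enable the WAVELET stage"
        )
    return Image


def jpeg2000_available() -> bool:
    try:
        _require_pillow()
        return True
    except WaveletCodecUnavailable:
        return False


def encode_j2k(grey16: np.ndarray, target_ratio: float) -> bytes:
    """Irreversible JPEG-2000 encode of a uint16 plane at a target ratio."""
    Image = _require_pillow()
    plane = np.ascontiguousarray(grey16, dtype=np.uint16)
    im = Image.frombuffer("I;16", (plane.shape[1], plane.shape[0]), plane.tobytes())
    buf = io.BytesIO()
    im.save(
        buf,
        format="JPEG2000",
        quality_mode="rates",
        quality_layers=[float(target_ratio)],
        irreversible=True,
    )
    return buf.getvalue()


def decode_j2k(data: bytes) -> np.ndarray:
    Image = _require_pillow()
    im = Image.open(io.BytesIO(data))
    arr = np.asarray(im)
    if arr.dtype != np.uint16:
        arr = np.clip(arr, 0, 65535).astype(np.uint16)
    return arr
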