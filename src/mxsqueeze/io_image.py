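"""Single-frame image interchange: 16-bit greyscale TIFF and integer FITS.

TIFF goes through tifffile (lossless, clip count and mask stashed in the
image description tag).  FITS is a self-written minimal single-plane
integer implementation — 2880-byte header blocks of 80-character cards,
big-endian data, BZERO offsetting for unsigned 16-bit — enough for
interoperability with astronomy codec tooling.
"""

from __future__ import annotations

import json
import warnings

import numpy as np
import tifffile

from .pipeline import Grey16Image

__all__ = ["write_grey16_tiff", "read_grey16_tiff", "write_fits", "read_fits"]


# ---------------------------------------------------------------------------
# TIFF


def write_grey16_tiff(image: Grey16Image, path) -> None:
    meta = {
        "clip_count": image.clip_count,
        "mask_packed": np.packbits(image.mask_payload.astype(np.uint8)).tobytes().hex(),
        "mask_shape": list(image.mask_payload.shape),
    }
    tifffile.imwrite(
        path,
        image.plane.astype(np.uint16),
        photometric="minisblack",
        description=json.dumps(meta),
    )


def read_grey16_tiff(path) -> Grey16Image:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        plane = page.asarray()
        if plane.dtype != np.uint16:
            raise ValueError(
                f"expected 16-bit greyscale TIFF, got {plane.dtype} "
                "(the 8-bit greyscale path is excluded: too aggressive for "
                "diffraction dynamic range)"
            )
        desc = page.tags.get("ImageDescription")
        clip_count = 0
        mask = np.ones(plane.shape, dtype=bool)
        if desc is not None:
            try:
                meta = json.loads(desc.value)
                clip_count = int(meta.get("clip_count", 0))
                if "mask_packed" in meta:
                    shape = tuple(meta["mask_shape"])
                    bits = np.unpackbits(
                        np.frombuffer(bytes.fromhex(meta["mask_packed"]), dtype=np.uint8)
                    )
                    mask = bits[: shape[0] * shape[1]].reshape(shape).astype(bool)
            except (ValueError, KeyError):
                pass
    return Grey16Image(plane, clip_count, mask)


# ---------------------------------------------------------------------------
# FITS (minimal, single integer plane)

_BLOCK = 2880


def _card(key: str, value, comment: str = "") -> bytes:
    if isinstance(value, bool):
        v = "T" if value else "F"
        text = f"{key:<8}= {v:>20}"
    elif isinstance(value, (int, np.integer)):
        text = f"{key:<8}= {value:>20d}"
    elif isinstance(value, float):
        text = f"{key:<8}= {value:>20.10G}"
    else:
        text = f"{key:<8}= '{value}'"
    if comment:
        text += f" / {comment}"
    return text[:80].ljust(80).encode("ascii")


def write_fits(image: np.ndarray, path, provenance: str = "written by mxsqueeze") -> None:
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValueError("write_fits expects a single 2-D plane")
    bzero = 0
    if arr.dtype == np.uint16:
        bitpix, out = 16, (arr.astype(np.int32) - 32768).astype(">i2")
        bzero = 32768
    elif arr.dtype in (np.int16,):
        bitpix, out = 16, arr.astype(">i2")
    elif arr.dtype in (np.int32, np.uint32, np.int64):
        if arr.dtype != np.int32 and (arr.min() < -(2**31) or arr.max() >= 2**31):
            raise ValueError("plane does not fit 32-bit FITS integers")
        bitpix, out = 32, arr.astype(">i4")
    else:
        raise ValueError(f"unsupported dtype {arr.dtype} for integer FITS")
    cards = [
        _card("SIMPLE", True, "conforms to FITS standard"),
        _card("BITPIX", bitpix),
        _card("NAXIS", 2),
        _card("NAXIS1", arr.shape[1]),
        _card("NAXIS2", arr.shape[0]),
        _card("BZERO", bzero),
        _card("BSCALE", 1),
        f"COMMENT {provenance}"[:80].ljust(80).encode("ascii"),
        "END".ljust(80).encode("ascii"),
    ]
    header = b"".join(cards)
    header += b" " * (-len(header) % _BLOCK)
    payload = out.tobytes()
    payload += b"\x00" * (-len(payload) % _BLOCK)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(payload)


def _parse_header(block_bytes: bytes) -> dict:
    cards = {}
    for i in range(0, len(block_bytes), 80):
        card = block_bytes[i : i + 80].decode("ascii", errors="replace")
        key = card[:8].strip()
        if key == "END":
            cards["END"] = True
            break
        if "=" in card[8:10]:
            value = card[10:].split("/")[0].strip()
            cards[key] = value
    return cards


def read_fits(path) -> np.ndarray:
    with open(path, "rb") as fh:
        data = fh.read()
    header = b""
    pos = 0
    cards: dict = {}
    while "END" not in cards:
        block = data[pos : pos + _BLOCK]
        if len(block) < _BLOCK:
            raise ValueError("truncated FITS header")
        header += block
        pos += _BLOCK
        cards.update(_parse_header(block))
    bitpix = int(cards["BITPIX"])
    naxis = int(cards["NAXIS"])
    if naxis != 2:
        raise ValueError("only single 2-D image planes are supported")
    n1 = int(cards["NAXIS1"])
    n2 = int(cards["NAXIS2"])
    bzero = int(float(cards.get("BZERO", "0")))
    dtype = {16: ">i2", 32: ">i4", 64: ">i8"}.get(bitpix)
    if dtype is None:
        raise ValueError(f"unsupported BITPIX {bitpix}")
    count = n1 * n2
    arr = np.frombuffer(data, dtype=dtype, count=count, offset=pos).reshape(n2, n1)
    arr = arr.astype(np.int64) + bzero
    if len(data) > pos + ((count * abs(bitpix) // 8 + _BLOCK - 1) // _BLOCK) * _BLOCK:
        warnings.warn("multi-extension FITS: returning the first image plane")
    if bzero == 32768 and bitpix == 16:
        return arr.astype(np.uint16)
    if bitpix == 16:
        return arr.astype(np.int16)
    return arr.astype(np.int32)
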