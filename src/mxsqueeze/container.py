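"""MXZ native container: one compressed stack per file.

Layout (all integers little-endian):

    magic  b"MXZ1\\n"
    uint64 header length, then that many bytes of UTF-8 JSON header
    uint64 mask payload length, then the zlib-compressed bit-packed mask
    uint64 blob count, then per blob: uint64 length + payload bytes

The JSON header records the pipeline string, original and current
geometry/scan, codec variant, and drop/clip bookkeeping, so a reader needs
nothing else to decode the file on any platform.
"""

from __future__ import annotations

import json
import struct

from .core import CompressedStack

__all__ = ["write_mxz", "read_mxz"]

_MAGIC = b"MXZ1\n"


def write_mxz(cstack: CompressedStack, path) -> None:
    header = json.dumps(cstack.header, sort_keys=True).encode("utf-8")
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack("<Q", len(header)))
        fh.write(header)
        fh.write(struct.pack("<Q", len(cstack.mask_payload)))
        fh.write(cstack.mask_payload)
        fh.write(struct.pack("<Q", len(cstack.blobs)))
        for blob in cstack.blobs:
            fh.write(struct.pack("<Q", len(blob)))
            fh.write(blob)


def read_mxz(path) -> CompressedStack:
    with open(path, "rb") as fh:
        if fh.read(5) != _MAGIC:
            raise ValueError("not an MXZ container")

        def take(n: int) -> bytes:
            data = fh.read(n)
            if len(data) != n:
                raise ValueError("truncated MXZ container")
            return data

        (hlen,) = struct.unpack("<Q", take(8))
        header = json.loads(take(hlen).decode("utf-8"))
        (mlen,) = struct.unpack("<Q", take(8))
        mask_payload = take(mlen)
        (n_blobs,) = struct.unpack("<Q", take(8))
        blobs = []
        for _ in range(n_blobs):
            (blen,) = struct.unpack("<Q", take(8))
            blobs.append(take(blen))
    return CompressedStack(
        header=header,
        mask_payload=mask_payload,
        blobs=blobs,
        codec_variant_id=header["codec_variant_id"],
    )
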