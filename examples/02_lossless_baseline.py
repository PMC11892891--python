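"""The byte-offset lossless baseline and what 'extra compression' means.

Every lossy ratio in this package is judged against the byte-offset codec,
because that is what a beamline detector already applies: storing the
as-collected data costs byte-offset bytes, not raw bytes.  The extra
compression ratio (ECR) of a lossy pipeline is therefore
byte-offset size / lossy size.
"""

import numpy as np

from mxsqueeze import decode_byte_offset, encode_byte_offset
from mxsqueeze.byteoffset import byte_offset_size, raw_size
from mxsqueeze.synth import preset, render_stack

# the dialect at a glance: small deltas cost one byte, large ones escape
blob = encode_byte_offset([0, 200])
print(f"[0, 200] encodes to {blob.payload.hex(' ')} (escape to 16-bit for 200)")
assert np.array_equal(decode_byte_offset(blob), [0, 200])

stack, _ = render_stack(preset("desk-small", seed=7))
s_raw = raw_size(stack)
s_bo = byte_offset_size(stack)
print(f"raw:         {s_raw/1e6:7.2f} MB  (4 bytes/pixel)")
print(f"byte-offset: {s_bo/1e6:7.2f} MB")
print(f"baseline ratio: {s_raw/s_bo:.2f}  (Poisson backgrounds of tens of counts")
print("                 have single-byte deltas almost everywhere)")
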