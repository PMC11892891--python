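"""Compose lossy pipelines and account for what they save.

Runs the desk-scale stack through binning, frame summing and H-transform
quantization in the combinations used for rotation-series archiving, and
prints the size accounting: total ratio (vs raw) and ECR (vs the
byte-offset baseline a beamline already has).
"""

from mxsqueeze import PipelineSpec, compress_pipeline, compression_report
from mxsqueeze.synth import preset, render_stack

stack, _ = render_stack(preset("desk-small", seed=7))

print(f"{'pipeline':<24}{'total':>8}{'ECR':>8}")
for pipeline in [
    "byteoffset",
    "bin2,sum2",
    "hcomp:16",
    "bin2,sum2,hcomp:16",
    "bin2,sum2,hcomp:64",
]:
    cstack = compress_pipeline(stack, PipelineSpec.parse(pipeline))
    rep = compression_report(stack, cstack)
    print(f"{pipeline:<24}{rep.total_ratio:>8.1f}{rep.ecr:>8.1f}")

# ECR x baseline = total by construction: the baseline ratio (~4 here)
# is compression the detector already delivered; ECR is what the lossy
# pipeline adds on top of it.
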