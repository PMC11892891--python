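# mxsqueeze

Lossy and lossless compression operators for rotation-series macromolecular
crystallography (MX) frames, with the machinery to measure what a lossy
pipeline did to the Bragg signal.

Modern pixel-array detectors produce finely φ-sliced rotation series (0.2°
per frame, 1200–1800 frames per data set) at rates that outrun both networks
and archives. Lossless codecs saturate near the entropy limit of the Poisson
background, so further savings must be lossy — and the question becomes
*which operators, at which settings, destroy the weak reflections an
experiment depends on*. This package implements the operators and the
evaluation tools for that question, exercised on synthetically generated
diffraction frames with exact per-peak ground truth. It is written for
beamline software developers and methods researchers; everything runs from
Python, with a small `mxsqueeze` CLI over the same functions.

## What is implemented

**Byte-offset baseline** (`mxsqueeze.byteoffset`) — the CBF lossless codec:
successive pixel deltas in one signed byte, escaping to 16/32/64-bit
little-endian integers via the markers `0x80`, `0x8000`, `0x80000000`.
Constant-ish 4-byte-per-pixel data compresses 4:1; MX-like Poisson
backgrounds land close to that. All lossy ratios are judged against this
baseline through the **extra compression ratio**

    ECR = S_byteoffset / S_lossy ,    total ratio = S_raw / S_lossy ,

because a beamline already stores byte-offset-compressed frames: only the
compression *beyond* that baseline is new.

**Reduction operators** (`mxsqueeze.pipeline`) — BIN*n* (sum *n*×*n* pixel
blocks; pixel size ×*n*, beam centre ÷*n*, gap rectangles remapped) and
SUM*m* (sum *m* consecutive frames; oscillation width and count time ×*m*).
Both conserve counts, commute exactly, and reduce the stored sample count by
*n*²·*m*. Remainders are dropped, never padded, and recorded.

**H-transform codec** (`mxsqueeze.htransform`) — an exactly invertible
integer Haar pyramid: each 2×2 block `[[p00,p01],[p10,p11]]` maps to

    h0 = p00+p01+p10+p11        hx = (p10+p11)-(p00+p01)
    hy = (p01+p11)-(p00+p10)    hc = p11-p10-p01+p00

with the `h0` plane recursed. Lossy operation divides every non-DC
coefficient by an integer *scale* (round half away from zero; scales 0/1
are lossless; the DC band is never quantized, so total counts survive).
Coefficients are entropy-coded per bit-plane with a quadtree significance
map. Detector gaps are median-filled before the transform and restored
exactly afterwards.

**External wavelet path** — frames convert to 16-bit greyscale
(`to_grey16`, clip counting) and go to a JPEG-2000 codec addressed by a
target ratio (Pillow/OpenJPEG when available; the stage errors rather than
silently falling back). TIFF and single-plane integer FITS writers are
included for interoperability with external codec tooling.

**Impact metrics** (`mxsqueeze.metrics`) — size accounting
(`compression_report`), averaged row profiles through a reflection
(`extract_profile`), a four-way per-peak survival classification
(`peak_impact`: *preserved / distorted / boosted / lost*, driven by
background-subtracted intensities, an I/σ(I) ≥ 3 detectability floor and a
shape correlation), stack-level summaries (`stack_impact`), and a
real-space R for density grids with total-density and variance
normalisations (`real_space_r`).

**Synthetic scenes** (`mxsqueeze.synth`) — rotation series with Poisson
backgrounds, Gaussian Bragg peaks split across frames by a Gaussian rocking
curve (partiality), and detector-gap stripes; every peak's per-frame
expected photon count is returned as ground truth. Presets cover a
desk-scale quick scene and 1800-/1200-frame series shapes; two frozen
benchmark scenes probe weak-peak survival under quantization.

## Worked example

Size accounting on the desk-scale synthetic series (512×512, 40 frames):

```
$ python examples/03_lossy_pipelines.py
pipeline                   total     ECR
byteoffset                   4.0     1.0
bin2,sum2                    8.0     2.0
hcomp:16                    14.0     3.5
bin2,sum2,hcomp:16          62.0    15.5
bin2,sum2,hcomp:64         140.9    35.2
```

The byte-offset baseline alone reaches 4:1 (the ECR is 1 by definition);
2×2 binning plus pairwise summing multiplies the raw reduction by 8; adding
H-transform quantization at scale 64 brings the total to ~141:1, i.e. an
ECR of ~35:1 beyond what the detector already delivered.

What that costs in signal, for a marginal weak reflection (~65 photons,
I/σ(I) ≈ 4):

```
$ python examples/04_weak_peak_impact.py
 scale class        I_before   I_after  I/sig
     4 preserved        40.4      44.9    3.3
     8 preserved        40.4      36.7    2.8
    16 distorted        40.4      45.6    4.7
    32 distorted        40.4      60.5    9.3
    64 lost             40.4       7.8    1.7
```

Mild quantization preserves the peak; intermediate scales distort and even
inflate it; scale 64 flattens the profile to block means and the reflection
drops below the 3σ detectability floor. Binning and summing *before*
quantizing concentrates each peak's photons into fewer, larger coefficients
and protects exactly these reflections — the motivation for recipes like
`bin2,sum2,hcomp:64` (exposed in the CLI as `recommended-archive`).

The CLI mirrors the library:

```
mxsqueeze synth --preset desk-small --seed 7 --out stack.h5
mxsqueeze compress --pipeline bin2,sum2,hcomp:16 stack.h5 out.mxz
mxsqueeze decompress out.mxz back.h5
mxsqueeze report stack.h5 out.mxz --json report.json
mxsqueeze profile stack.h5 --center 391,148 --rows 6 --half-width 12
```

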