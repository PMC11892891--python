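# Methods

This note records the models, conventions and numerical choices behind
mxsqueeze, and what the synthetic benchmarks do and do not establish.

## Data model and conventions

Frames are planes of signed 32-bit photon counts (modern integrating
detectors deliver up to 32-bit dynamic range) with an explicit boolean
validity plane; detector gaps and defective pixels are invalid. Sentinel
values (by default the all-ones value of the stored dtype, e.g.
`0xFFFFFFFF` for uint32) exist only at I/O boundaries: `sentinel_to_mask`
and `mask_to_sentinel` convert between the two representations, and the
round trip is the identity whenever no valid count equals the sentinel
(converting a valid pixel that does carry the sentinel value is an error,
because the encoding would be ambiguous). Codecs and metrics never see a
sentinel — a saturation value leaking into a wavelet transform would
dominate the coefficient budget and corrupt the bitstream.

Coordinates are 0-based and row-major; intervals are half-open; the beam
centre is stored in pixel units so that binning updates are pure divisions.
All container fields are little-endian.

## Byte-offset codec

The dialect follows the CBF convention: running deltas from a previous
value initialised to 0; a delta in [−127, 127] costs one signed byte;
otherwise the marker `0x80` introduces a 16-bit little-endian delta in
[−32767, 32767]; the 16-bit marker `0x8000` introduces a 32-bit delta; the
32-bit marker `0x80000000` introduces a 64-bit delta. Worst case is
15 bytes per value (all three markers plus an 8-byte delta). The raster is
a single row-major stream without row restarts, and the encoded stream is
the sentinel-substituted on-disk raster, so the measured baseline size is
the stream a beamline would actually store. Ratios are computed on payload
bytes only, excluding container overhead, which makes the 4:1 figure for
4-byte-per-pixel data with single-byte deltas exactly recoverable and
container-independent.

## H-transform codec

The forward transform is the integer Haar pyramid without divisions
(sums and differences only), which makes it exactly invertible: each pixel
is recovered as a multiple-of-4 combination of the four block
coefficients, and the inverse applies a floor-of-quarter at each level.
Input planes are padded to the next power-of-two square by edge
replication (zero padding would inject step edges into the coefficient
budget) and cropped on decode.

Quantization divides every non-DC coefficient by the integer scale with
round-half-away-from-zero. The DC coefficient is never quantized, so the
reconstruction preserves the total count of the plane to within the
rounding of the other bands (measured < 2% drift at scale 64 on Poisson
planes). Scales 0 and 1 are bit-exact on arbitrary integer planes,
including negatives and non-square shapes.

The entropy stage codes coefficient magnitudes bit-plane by bit-plane,
most significant first. Each bit-plane is traversed breadth-first with a
quadtree significance map (a zero block at any level costs one bit), and
one sign bit per nonzero coefficient follows. The stream is bit-packed
with a small fixed header (magic, variant id `hqt1`, scale, level count,
original shape). The dialect is self-contained and deliberately *not*
byte-compatible with the astronomy Hcompress program: what is modelled is
the transform and the scale semantics, which is what the measured
size/fidelity trade-offs depend on. Decode-time smoothing is not applied.

Invalid pixels are filled with the median of their valid 5×5 neighbours
before the transform (pixels deep inside a gap fall back to the global
valid median); the validity plane travels losslessly alongside the
payload, and decompression restores invalid pixels to zero/invalid, so no
information is invented where the detector saw nothing. Lossy
reconstructions are clipped at zero on valid pixels to preserve the
non-negativity invariant of count data.

## Reduction operators and metadata

BINn sums n×n blocks; a superpixel is invalid iff any source pixel is
invalid. SUMm sums m consecutive frames; oscillation width and count time
scale by m. Non-divisible remainders (rows/columns under BIN, trailing
frames under SUM) are dropped rather than padded — padding would bias the
sums — and every drop is recorded in the container header. Geometry
updates under BINn: pixel size ×n, pixel counts ⌊·/n⌋, beam centre ÷n, gap
rectangles mapped to the superpixel intervals that overlap them. The two
operators are linear sums over disjoint index sets and therefore commute
exactly; pipelines apply BIN before SUM purely because it is cheaper.
Summed counts stay in signed 32-bit; exceeding 31 bits raises rather than
wrapping.

The 16-bit greyscale conversion for external wavelet codecs clips counts
at 65535 and reports the clip count; the 8-bit path is deliberately not
offered (too aggressive for diffraction dynamic range). The JPEG-2000
stage is an adapter contract — target compression ratio in, payload out —
fulfilled by Pillow/OpenJPEG when present; requesting it without a codec
raises an instructive error, never a silent fallback.

## Impact metrics

`compression_report` measures payload bytes: raw (4 bytes/pixel as
collected), byte-offset (the baseline), and lossy (codec payloads + mask +
header). The ECR uses the byte-offset size of the *original,
pre-reduction* stack as numerator, so `ecr × baseline_ratio ≡ total_ratio`.

`peak_impact` integrates background-subtracted intensity in a circular
window of radius 3σ_px around the peak, with background mean and σ from
the annulus between 3σ_px and 5σ_px. Classification priority: **lost** if
the intensity in the test frame fails `I > 3·σ_annulus·√n_window` (the
conventional I/σ(I) ≈ 3 weak-reflection floor); else **boosted** if the
intensity inflated by more than τ_boost = 0.5; else **distorted** if the
windowed shape correlation falls below ρ_min = 0.9; else **preserved**.
Two deliberate choices:

* the detectability floor uses the *reference* frame's annulus σ. A codec
  that flattens the background along with the peak must not thereby make
  the peak "detectable" against its own smoothed residue; the floor is the
  noise level of the original measurement.
* bit-identical window and annulus classify as preserved regardless of
  SNR: the classification scores what the compression did, and untouched
  data did nothing, however marginal the peak.

Reflection profiles average n rows through the peak (default 6 on native
frames, 3 on binned frames, where the reflection spans half as many rows);
invalid pixels are excluded per column and fully-invalid columns are
flagged as missing (NaN).

`real_space_r` offers two normalisations for density-grid agreement:
`total_density` (Σ|ρ_ref − ρ_test| / Σ|ρ_ref|) and `variance`
(Σ(ρ_ref − ρ_test)² / Σ(ρ_ref − mean)²), the latter scoring discrepancy
against the contrast of the reference map, which makes maps from
non-cognate coordinates comparable; a helper averages the two. The
variance-mode numerator (squared differences) is this package's stated
choice.

## Synthetic scenes: what they emulate and what they do not

Pixel (r,c) of frame i is an independent Poisson draw with mean
`b(r) + Σ_p λ_{p,i}·G_p(r,c)`, where `b(r) = base·exp(−r/decay) + floor`
is radially symmetric about the beam centre, `λ_{p,i}` is the peak's total
intensity times the Gaussian rocking-curve mass inside the frame's φ
interval, and `G_p` is a unit-mass isotropic Gaussian truncated at 5σ
(normalised on the full truncation window, so peaks at the detector edge
lose the mass that falls off rather than having it invented). One PCG64
generator seeded from the scene seed is consumed frame-major, then
pixel-raster, so identical configurations are bit-identical across
platforms. Default gaps are two horizontal 10-pixel stripes, mimicking
multi-module detectors.

The generator reproduces the statistical structure the codecs act on —
slowly varying background, localized peaks, partiality, gaps — and none of
the physics it does not need: no Ewald-sphere geometry, polarization,
Lorentz factor, diffuse scattering, ice rings, or per-module orientations.
Passing benchmarks here shows how the codecs treat signals of this
structure and strength; it does not certify downstream structure solution
on real data, which involves integration software, scaling and phasing
steps outside this package's scope.

Presets: `desk-small` (512×512, 40 frames at 0.2°, background of tens of
counts, 60 peaks over three intensity decades) is the quick desk-scale
stand-in for an Eiger-class module array (~6× per side scale-down);
`lysozyme-like` (1800 frames, 360° total, dense strong peaks) and
`rt-like` (1200 frames, 240° total, sparser weaker peaks) reproduce the
series shapes of real acquisitions at ~12× per-side scale-down, with the
scale factor recorded in the config. Peak layouts are fixed per preset
(internal layout seed); the user seed drives only the Poisson sampling.

## The weak-peak benchmarks and their calibration

Two frozen scenes probe quantization impact; their parameters were chosen
once, from the signal-to-noise regime in which weak reflections are
findable but vulnerable, and are part of the scene definitions:

* `hcomp_benchmark_scene` — 160×160, 8 frames, flat background of
  1 count/pixel (typical of fine φ-slicing, where the per-frame background
  is a few counts), 26 weak peaks of 100 photons (σ_px 2.0, I/σ(I) ≈ 5)
  and 4 strong peaks kept ≥ 14 px from every weak peak so their tails
  never contaminate a weak peak's background annulus. In this regime
  scales ≤ 32 lose essentially nothing and scale 64 swallows a
  substantial fraction of the weak peaks.
* `marginal_peak_scene` — a single 65-photon reflection (I/σ(I) ≈ 4) at
  (31.5, 31.5), which straddles a block corner of every pyramid level, so
  its photons split across coefficients at all scales: scale 4 preserves
  it, scale 64 zeroes every coefficient it owns and the reflection is
  lost.

Three behaviours of the codec family are worth stating because they are
genuine, not artifacts:

* **Per-peak degradation is not monotone in scale.** Quantization rounds
  half away from zero, so a coefficient just above half a step is
  *inflated* to a full step — individual reflections can be boosted at an
  intermediate scale and swallowed at the next. Plane-level RMS error,
  payload size and the benchmark scene's lost fraction are monotone; the
  mean intensity error shows a transient inversion at intermediate
  scales, and the tests assert the gross trend for that quantity.
* **Backgrounds near 100 counts/pixel protect everything.** When the
  background σ is large, any reflection that clears the detectability
  floor carries enough photons that its coefficients survive even scale
  64. Weak-peak loss is a low-background phenomenon, which is why the
  benchmark scene uses ~1 count/pixel.
* **Pre-reduction protection is an intensity statement, not a floor
  statement.** BIN2+SUM2 concentrates each peak's photons ×4 per
  coefficient while the quantization step stays fixed, so weak-peak
  intensities survive coarse quantization much better (the benchmark
  asserts mean |ΔI|/I at scale 64 with pre-reduction ≤ without). The
  integrated detectability floor, by contrast, *rises* under summing
  (background sums m-fold while the integrated peak intensity is fixed,
  so the floor grows ~√m), so lost-fraction comparisons across geometries
  mix codec damage with floor arithmetic and are not asserted.

## Numerical choices and degenerate inputs

Quantization rounding is half away from zero (integer arithmetic,
`(2|c| + s) // 2s`). Gap filling uses the 5×5 valid-neighbour median with
a global-median fallback. Profile windows must fit inside the frame
(error otherwise); fully invalid profile columns are NaN. An annulus with
no valid pixel is an error. `real_space_r` rejects non-finite grids,
mismatched shapes, and a flat reference in variance mode (zero
denominator). Empty stacks encode to zero payload bytes. Truncated
byte-offset payloads and corrupted H-transform bitstreams raise with the
byte offset reached. `validate_stack` never raises; it returns one
violation string per broken invariant, naming the frame.

## Problem sizes

The test suite renders the desk-scale series (512×512 × 40 frames) once
per session and the benchmark scenes (160×160 × 8; 64×64 × 3) per test;
the full suite completes in well under a minute on one CPU. The
acceptance script renders the desk-scale series once and byte-offset
encodes 10.5 M pixels, a few seconds end to end. Full-size series
(3110×3269 × 1800) are out of desk scope by design; all operators are
vectorised and scale linearly in pixel count, so nothing in the
implementation is specific to the reduced sizes.

## Known limitations

Single-panel geometry only (no per-module orientations); rotation scans
only (no still/serial metadata); binning/summing are not invertible and
no super-resolution is attempted; the wavelet stage depends on an
external JPEG-2000 codec; the H-transform bitstream is this package's
dialect, not the astronomy program's; electron-density grids are inputs
to `real_space_r`, not computed from diffraction data; saturation is
handled by mask propagation only.
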