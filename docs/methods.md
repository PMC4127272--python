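# Methods

## The codec in one paragraph

An 8-bit grayscale image is decomposed by a pyramidal 2-D DWT into detail
planes (horizontal, vertical, diagonal) and an approximate plane; each
plane is uniformly quantized, run-length coded into (value, count)
"cosimilar" pairs, and the interleaved pair sequence is compressed by an
autoassociative single-hidden-layer network whose bottleneck activations,
8-bit quantized, are the stored representation together with the decode
weights and the exact run counts. Decompression mirrors every stage:
hidden codes → sequence → pairs → quantized plane → inverse DWT → pixels.

## Model and assumptions

**Content model.** The pipeline assumes piecewise-near-constant imagery:
long raster runs of equal values (flat anatomy and background) are what the
pair coder converts into a short stream, and smooth regions are what makes
the approximate subband compact. On i.i.d.-noise-like content the pair
stream can *exceed* the raster size (each pixel its own run); the harness's
constant-vs-random CR ordering test documents this failure mode.

**Transform.** `pywt.wavedec2/waverec2` with orthonormal Haar, L = 1 by
default. Haar fits the two-tap "successive high/low pass" filter-bank
architecture, is orthonormal (energy is preserved, so coefficient-domain
coding error equals pixel-domain error), and has no boundary spread. Other
discrete wavelets and deeper pyramids are configurable. Odd dimensions use
symmetric half-sample extension with the original shape recorded for exact
cropping; perfect reconstruction holds to < 1e-8 for every 8-bit image and
L ≤ 3 (property-tested, and re-measured by the acceptance script).

**Quantization.** Uniform scalar, round-to-nearest with ties away from
zero. Defaults: step 0.5 for the approximate plane, 1.0 for detail planes —
the approximate plane carries ~98 % of the energy on phantom content, so it
gets the finest step; detail coefficients of near-flat content are mostly
zero and tolerate the coarser bin. Dequantization error is bounded by
step/2 per coefficient, i.e. at most ~0.25 intensity levels after the
inverse transform under defaults — negligible next to the neural stage.

**Pair coder.** Raster (row-major) scan, maximal runs. "Cosimilar" for
real coefficients means equal after quantization. Runs longer than 255 are
split into repeated pairs before the neural stage so that counts share the
values' dynamic range; the lossless mode stores unsplit maximal runs as
LEB128 varints (zigzag for signed values).

**Neural coder.** One network per stream (per subband in spectral mode).
Chunks of n = 16 interleaved sequence values are normalized to [-1, 1]
(affine map 2x/s_max − 1 for nonnegative streams, x/s_max for signed ones;
s_max is the stream maximum, recorded in the header). The encoder weight
matrix is initialised from the chunk Gram matrix Σxxᵀ: its top-k unit
eigenvectors (sign fixed: largest-magnitude entry positive) form W_enc and
their transpose W_dec. This eigen-reading is the only dimensionally
consistent interpretation of a Hebbian outer-product weight rule feeding a
k-unit hidden layer, and it is exactly principal-component initialisation:
in the linear regime its reconstruction error *equals* the rank-k SVD
optimum (asserted against a direct SVD oracle). Backpropagation
(full-batch least-mean-square descent with backtracking, so the reported
error never increases) then refines both matrices through the tansig hidden
layer, stopping at MSE ≤ 0.1 (normalized units) or 50 epochs. Training is
fully deterministic; identical inputs give bit-identical weights.

**What is stored.** Per lossy stream: the exact run counts (varints), the
n×k decode weights (32-bit floats), and the hidden codes quantized to 8
bits over the tansig range. Decoding needs no encoder weights and no
retraining — the container is self-contained. Run counts are structural: a
single miscounted run would shift every subsequent pixel of the plane, so
they are carried exactly in a side stream while the network still sees the
full interleaved sequence; only run *values* carry neural error, and that
error stays local to its run.

## Parameters

| parameter | default | units | why |
|---|---|---|---|
| `wavelet` | haar | — | orthonormal two-tap pair; see Transform |
| `levels` | 1 | — | one level = the four planes C1–C4; recursion optional |
| `q_approx` | 0.5 | intensity | finest step for the energy-carrying plane |
| `q_detail` | 1.0 | intensity | detail planes are near-zero on target content |
| `chunk` (n) | 16 | values | short enough for per-image training sets |
| `k` | 8 | units | the compression knob; n/2 halves the code rate |
| `goal` | 0.1 | normalized MSE | training stop criterion |
| `max_epochs` | 50 | epochs | training budget |
| `learning_rate` | 0.2 | — | initial step; backtracking adapts it |
| run cap | 255 | count | keeps counts inside the value dynamic range |

## The phantom generator

Phantoms emulate what matters to this codec about clinical images: a
dominant flat background, a handful of piecewise-constant "anatomical"
regions from a small intensity palette, optionally a smooth illumination
gradient and additive Gaussian noise, clipped and rounded to 8 bits.
Regions sit one-per-cell on a jittered grid, and every random draw happens
before any area-dependent computation, so sweeping the background fraction
only rescales radii around fixed centres — which makes run-length
redundancy, and hence lossless CR, strictly monotone along the sweep.

What the phantoms do **not** model: acquisition physics (projection,
k-space), texture, anatomical shape statistics, 16-bit dynamic range.
Passing tests therefore demonstrate the codec's contracts (exact inverses,
determinism, rate behaviour under controlled redundancy, the rank-k
optimality bound) on content with the assumed redundancy structure — not
diagnostic quality on real scans.

Defaults are noiseless (sigma = 0): noise destroys runs and is kept as an
explicit stress case. The rate-matched spectral-vs-direct comparison suite
instead uses sigma = 1.0 and gradient amplitude 16, because on noiseless
phantoms the pixel-domain pair stream is so small that no hidden size lets
the direct artifact reach the spectral artifact's byte size — the
rate-matching protocol (sweep the direct mode's k until container sizes
agree within 5 %) needs both codecs to span overlapping rates, and mild
noise plus a gradient is also the more realistic acquisition model.

## Numerical choices and degenerate inputs

- Quantizer ties away from zero; the same rule rounds decoded values.
- Decoded run values are clipped to the stream's recorded [u_lo, u_hi].
- Eigenvector signs and the backtracking schedule are deterministic; no
  randomness enters the codec path at all, the seed is recorded for
  provenance.
- Zero-filled or corrupted hidden codes still decode to a valid image of
  the declared dimensions (counts are exact); genuinely inconsistent
  containers (truncation, count mismatches, block-size errors) raise
  stage-named errors.
- 1×1 images, constant images, odd dimensions and empty payload containers
  are all exercised in the tests.
- Images deeper than 8 bits are rejected, never rescaled, to keep the CR
  and PSNR accounting on the 8-bit scale; multi-channel inputs are reduced
  by the BT.601 luminance weights.
- "Original bytes" for CR is m·n (the raw 8-bit raster), not the input
  file's on-disk size, so ratios do not depend on the source file format.

## Known limitations

- The 0.1 training goal is a loose stop: in normalized units it corresponds
  to a large value error, so default lossy quality sits around 19–20 dB on
  128×128 phantoms. Tightening `goal` (and raising `k`) buys quality up to
  a ceiling near 30 dB set by the 50-epoch budget and the tansig layer;
  the lossless mode exists precisely because the neural path is not meant
  for bit-exact retrieval.
- The rate-matched advantage of the spectral mode over the direct mode on
  the comparison suite is consistent but small (~0.2 dB); it reflects the
  transform concentrating energy before the bottleneck, not a large-margin
  win.
- One network is trained per stream per image; encoding cost grows with
  subband count. Problem sizes used throughout the tests and the
  acceptance script (phantoms from 64×64 to 512×512, 20-image suites,
  500-chunk training sets) keep the full suite in the low seconds on one
  CPU.
- The JPEG 2000 baseline depends on Pillow's optional OpenJPEG support; the
  harness records it as a failed cell where unavailable. No comparison in
  the package's own guarantees depends on it.
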