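# Methods

This note documents the models, numerical choices and open design
decisions behind `wce3dct`, in the order data flows through the codec.

## Bayer geometry

The CFA phase is fixed to RGGB with 0-based indexing (even rows
R,G,R,G,…; odd rows G,B,G,B,…). Green samples are split by row parity:
G1 lives on red rows, G2 on blue rows, preserving the row pairing of the
4×4×4 stack R–G1–G2–B. Images whose dimensions are not multiples of 8
are rejected rather than padded — the target sensor format (480×480)
needs no padding and any padding policy would be invented semantics.

Demosaicing is bilinear (deterministic, pluggable). Border pixels are
interpolated after padding the mosaic by two pixels with *reflection*
(`np.pad(mode="reflect")`): plain edge replication would break CFA
parity and interpolate a border pixel from wrong-channel neighbours,
whereas a two-pixel reflection maps every padded site onto a
same-channel sample. At native sites the kernels have unit centre
weight, so `demosaic` never alters a pixel's own channel sample and
re-mosaicing a demosaiced image is exact.

## Transform

`dct3d_oracle` evaluates the definition with prefactor 1/8 and
C₀ = 1/√2. That normalisation is not orthonormal; the 1D matrix
T[i,n] = C_i A(n,i)/2 satisfies T Tᵀ = I/2, so the inverse carries a
unit prefactor with the C's inside the sum. The closed-form inverse was
validated numerically against inversion of the 64×64 transform matrix.

The fast butterfly uses the identity tan(π/8) = √2 − 1,
cot(π/8) = √2 + 1: after the even/odd split (s = sums, d = differences),

    X1' = (d0 − d1) + √2·d1,   X3' = (d0 − d1) − √2·d1

equal the odd-frequency outputs divided by cos(π/8) and sin(π/8). With
the shared even part this costs 13 additions and 4 shifts, of which 4+4
realise the single √2 multiply through the dyadic expansion 1.4140625.
The per-coefficient diagonal scale
[1/(2√2), cos(π/8)/2, 1/(2√2), sin(π/8)/2] is applied once at the end of
the three separable passes (as S_i·S_j·S_k), so the fast output matches
the reference transform directly and quantization tables need no
folding; in a hardware encoder the same constants would be absorbed into
the table.

Precision: |√2 − 1.4140625| = 1.51×10⁻⁴ absolute, 1.07×10⁻⁴ relative.
The "precision loss below 1.5×10⁻⁴" guarantee holds in the relative
sense (the constant itself exceeds the bound in the absolute sense by
0.7%). Propagated through three separable passes the fast/reference
disagreement stays below 0.03 per coefficient on 8-bit blocks; the test
suite asserts a conservative 0.5.

The decoder inverts the butterfly dividing by the *same* dyadic constant
(it runs in vitro, with no arithmetic budget), so fast round trips are
exact to float noise rather than accumulating the approximation twice.
Arithmetic is float64 throughout — there is no fixed-point bit model;
shifts are exact multiplications by dyadic constants and are *counted*
as shifts by the `OpCounter`.

A level shift of −128 is applied before the forward transform and undone
(with clipping to [0,255]) after the inverse, recorded as a header flag
so decoders agree. It centres 8-bit data and keeps DC magnitudes small.

## Quantization

Steps are positive integers; the shipped default uses powers of two in
{8, 16, 32, 64} with DC steps of 8, transcribed from its published
digit-string form (the tokenisation is unambiguous: every legal value is
determined by its first digit) and frozen as a code constant.
Rounding is half-away-from-zero, keeping the error symmetric and bounded
by step/2 per coefficient. Coarsening is lattice-monotone: doubling a
step can never reduce a coefficient's error because the 2Q lattice is a
sub-lattice of Q.

## Rate-distortion table search

The objective is J(Q) = MSE(Q) + λ·BR(Q), with MSE measured in the
spatial block domain against the original pixels and BR the exact
entropy-coded bits per pixel (header excluded). Hyper-parameters the
source method leaves open were fixed to standard GA/PSO practice:
population 32, tournament selection of size 3, mutation by resampling a
chromosome from the allowed step set at rate 0.05, single-point
crossover at rate 0.8, inertia w = 0.7, attraction gain k = 0.5.
Chromosomes are constrained to powers of two in {1,…,128}; after each
PSO move they snap to the nearest allowed value (ties to the smaller
step). The per-generation order is the literal loop "mutation,
selection, crossover, selection", followed by the PSO acceleration;
elitism re-injects the best-ever individual after both phases, making
the best-so-far trace monotone by construction. Velocities follow
surviving individuals through selection and reset to zero for crossover
offspring (the source leaves this unspecified). λ is a free
configuration knob; choosing it to hit a PSNR floor is an outer sweep,
not hard-coded.

## Entropy layer

The four (0,0,k) coefficients are the per-plane DC values and are coded
by per-plane DPCM against the previous block in raster order (predictors
reset at stream start): size-category Huffman code plus one's-complement
amplitude bits. AC coefficients are (run, size) symbols with ZRL and
EOB, JPEG-style, over the 60-long scanned vector. Huffman tables are
built once, deterministically, from a fixed geometric frequency model
(weights 2^(−0.7·run − size), a heavy EOB, category-0 DC dominant) —
proper prefix-free Huffman codes without requiring a two-pass encoder.
Amplitude categories up to 15 are supported; larger levels raise a
range error rather than corrupting the stream.

The scan order ranks AC positions by decreasing mean |coefficient| over
a corpus (ties: decreasing variance, then ascending (i+j+k, k, j, i)),
computed on *unquantized* coefficients. The shipped default was derived
from the seeded synthetic corpus (8 images, 128×128, seeds 0–7) and
frozen; a test regenerates it from the same corpus to guard drift. Note
that after removing the four DC positions only seven AC positions with
i+j+k ≤ 2 exist; all seven occupy the first ten slots of the default
order — the strongest energy-compaction statement the index set allows.

The container is this artifact's own format: magic `W3DC`, version,
dimensions, a level-shift flag, the 64-byte table and 60-byte scan order,
then the bit-packed payload (big-endian, byte-aligned only at the end).

## Deblocking

MSDS for adjacent blocks A, B along an in-plane axis sums, over the 4×4
boundary face (colour planes included),
[(B₀−A₃) − ((A₃−A₂)+(B₁−B₀))/2]² — the cross-boundary step minus the
mean one-sided slope, zero on any linear ramp. z-boundaries are never
filtered; z is the colour axis.

The dither is the negated centroid shift of a uniform quantizer under a
Laplacian coefficient prior with rate ξ = 52/F²:
Δ = −(Q/2)(coth(x) − 1/x), x = ξQ/2. It lies in (−Q/2, 0], reaches
−Q/2 as F → 0 and decays as −ξQ²/12 for strong coefficients, which is
what makes real edges insensitive. (A literal transcription with the
minus sign inside coth alone diverges quadratically in F and destroys
that discrimination; the sign is read as applying to the whole
expression.) Numerics: coth(x) − 1/x is evaluated by series (x/3) below
x = 10⁻⁴ and saturates correctly at the ξ → ∞ limit without special
cases.

SMSDS is the relative MSDS change under that dither, with 0 returned for
an exactly zero base MSDS. It is a ratio and therefore unbounded above:
boundaries with near-zero base MSDS can score arbitrarily high, so even
a nearly losslessly coded image receives mild filtering at its smoothest
boundaries (measured: the change stays above 40 dB PSNR-equivalent on
the synthetic corpus). No clamping is applied — none is prescribed.

ε = SMSDS·η·Q(i,j,k) (a product; η = 0.5, configurable): ε must grow
with the quantization step, which rules out the alternative reading of
η as an exponent base. The filter weights are the ridge-regression
solution α = (F_C−m)²/((F_C−m)²+ε), β = (1−α)/2, so α + 2β = 1 exactly;
the degenerate 0/0 case (F_C = m and ε = 0) takes α = 1, which changes
nothing since F_C already equals the blend target.

Processing order: all x-axis boundaries in raster order, then all
y-axis boundaries, write-backs applied sequentially in place (the block
C seen by a later pair includes earlier write-backs; a pixel on both an
x- and a y-boundary is simply overwritten last). The spectra F_A, F_B
guiding each pair are always the *transmitted* (dequantized) ones, which
stay fixed throughout. Deblocking operates on the 3D-block grid before
mosaic disassembly and demosaicing, matching the decoder's stage order.

## Synthetic scenes

The generator emulates the documented statistics of WCE frames rather
than their appearance: a shared low-pass luminance field mixed into all
three channels at weight 0.93 (pairwise ρ ≈ 0.99 with defaults, above
the 0.9 floor real data shows), mean hue (185, 125, 92) giving
R > G > B, and four structure primitives — smooth fold ridges, dark
red-tinted vessel strokes, band-pass villi texture in elliptical
patches, and bright bubble rims — that exercise the deblocker's
edge/artifact discrimination. Channel gains (30, 24, 19), field
smoothness 20 px and additive Gaussian noise σ = 1 were calibrated so
the default corpus sits in the quality corridor the shipped quantization
table was designed for (CR ≈ 40:1 at ≈ 39 dB Bayer-domain PSNR;
CR > 10 and PSNR > 38 over 20 seeds).

What passing tests do and do not show: the generator reproduces the
correlation structure, hue ordering, smoothness scale and the presence
of localised genuine edges, but not specular highlights, vignetting,
motion blur, demosaic-era artifacts or realistic sensor noise. Synthetic
scenes are *simpler* than tissue, so absolute CR figures here exceed
what real data would give; conclusions supported by the suite are about
correctness and qualitative behaviour (losslessness, discrimination,
monotone search, corridor sanity), not clinical performance.

## Metrics

PSNR = 10·log₁₀(255²/MSE), with an infinite sentinel for identical
images; the headline metric is Bayer-domain PSNR (the codec's native
domain), with RGB-domain PSNR after bilinear demosaic reported
alongside. CR is raw mosaic bits (8/pixel) over total stream bits,
header included.

## Known limitations

- Single CFA phase (RGGB); no padding of odd-sized images.
- Fixed Huffman tables; no adaptive or arithmetic coding, no rate control.
- The deblocker's sequential in-place write-backs make the result depend
  on the (documented) processing order.
- The quality corridor is a property of the synthetic corpus; real-data
  rates and distortions will differ.
- Test problem sizes (96–480 px images, reduced search runs of
  population 16 × 30 generations) are the package's chosen defaults for
  a fast, deterministic suite; all are configurable upward.
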