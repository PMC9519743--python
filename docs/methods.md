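# Methods

## What the simulator models

The package targets optical-resolution photoacoustic microscopy of
superficial microvasculature, raster-scanned by a fast galvanometer sweep
(x) and a slow linear step (y). The simulator's default geometry follows
the system the correction method was developed for: a 1.1 mm x 1.0 mm
field of view, 250 fast-axis pixels (4.4 µm pitch), slow-axis steps of
4 µm for bidirectional scans and 2 µm for unidirectional scans. The
unidirectional acquisition simulates both sweep directions but keeps only
forward lines, so both protocols land on the same 250-row grid at the same
physical y positions — this row correspondence is what makes the pairs
pixel-aligned by construction, with no registration step.

**Scenes.** Vessels are smooth cubic-spline curves grown by a correlated
random walk, with linearly tapering radius (6–16 µm at the root), random
amplitude in [0.6, 1], and a ~50% chance of one side branch. A rejection
loop re-draws any scene whose vessel area fraction on a 2 µm raster falls
outside [1%, 60%]. Vessels have Gaussian cross-sections; the lateral PSF
is folded in analytically by adding variances (vessel σ ⊕ PSF σ), with the
PSF FWHM defaulting to the diffraction limit 0.51·λ/NA = 8.5 µm (NA 0.032,
532 nm). Scenes are rasterized to a 1 µm reference grid (2 µm in the
scaled test runs) via a nearest-centerline-point lookup (cKDTree over
densified curve points carrying local radius); acquisition samples this
grid bilinearly, so sub-pixel trajectory errors produce real intensity
changes.

**Timing jitter.** The instrument's misalignment mechanism — non-uniform
time intervals between scan points — is modeled on backward lines only:

    x_backward = reverse(grid) + (µ + A·sin(2π·j/n_lines) + ε_j)·L,
    then x → x + Σ_k a_k·L·sin(kπx/L)

with µ the mean phase lag, A a slow drift across the frame, ε_j ~ N(0, σ)
per-line noise, and the odd-harmonic warp supplying the *nonlinear*
("intersecting") component. Defaults µ = 0.004, σ = 0.002, a₁ = 0.003,
A = 0.002 (all fractions of the fast-axis span) displace backward lines by
~1 px and bring pairwise SSIM to ≈ 0.9 — visually obvious vessel doubling
without destroying structure. The warp must keep the trajectory strictly
monotonic; fold-over raises an error. These values are a stand-in: the
real instrument's jitter statistics are not published, so no claim is made
that the defaults match any particular scanner.

**Noise.** Additive Gaussian noise with σ = 0.0045 on [0, 1] amplitudes
(~47 dB peak SNR) is applied independently to each acquisition. Noise is a
parameter separate from the jitter model; the zero-jitter equivalence
tests disable it to assert exact input/target equality.

**3D path.** With `n_depth > 0` each vessel carries a fractional depth;
its scanned 2D image is spread along z by a Gaussian axial PSF (FWHM
defaulting to 0.88·c/(f₀·BW) = 113 µm at 20 MHz, 60% bandwidth), and
vessel contributions combine by maximum. This produces A-line volumes
whose MAP equals the 2D simulation of the same scene.

## Network

The generator is a three-scale fully-dense U-Net. Channel width and dense
growth rate double per scale (base 36, growth 17 at full resolution);
each scale has one dense block of four 3x3 convolutions (each layer sees
the concatenation of the block input and all previous outputs), a stride-2
3x3 convolution for learned downsampling, and on the decoder side a 1x1
convolution + pixel-shuffle for upsampling. Each decoder block's input
concatenates (i) the upsampled features, (ii) the U-Net skip from the
matching encoder stage, and (iii) a multiscale branch: the raw input
median-pooled by 2^s and passed through a 1x1 convolution (16 channels).
All convolutions use reflective 'same' padding and LReLU (slope 0.2); the
head is a 1x1 convolution + sigmoid. The discriminator is five sequential
3x3 convolutions (widths 65/130/260/520, strides 2/2/2/1/1, sigmoid patch
map; the mean patch score is the scalar decision).

Channel widths are not published; only the parameter budgets are. The
reference widths were calibrated with `scripts/calibrate_model.py` to land
on 7,599,365 generator and 1,603,291 discriminator parameters (within
0.2% of the 7.6 M / 1.6 M budgets). The multiscale branches feed the
decoder only, the discriminator is unconditional (it scores a single
image, not an (input, candidate) pair), and the generator output uses a
sigmoid — all three points where the published description admits more
than one reading; each choice is the simplest consistent one.

The entire network stack (convolution via im2col + BLAS, activations,
pixel shuffle, Adam, He-normal init, backprop) is implemented in
`biraster.nn` on numpy with explicit backward passes, verified by
finite-difference gradient checks in the test suite.

## Training

Alternating updates: one discriminator step (real batch, then detached
fake batch) followed by one generator step per mini-batch. The generator
loss is λ·(−log D(G(x))) + ν·MAE + (1−λ−ν)·(1−SSIM) with defaults
λ = 0.05, ν = 0.60 — reconstruction terms dominate, the adversarial term
sharpens. The published coefficient values live in supplementary material
that is not available, so both are exposed in config. The SSIM term uses
an 11x11 Gaussian window (σ 1.5) applied with zero padding, which makes
the windowing operator self-adjoint and the analytic gradient exact; the
metric-side SSIM uses the standard valid-window convention, and the two
agree away from borders.

Optimization is Adam (moments 0.5/0.999, L2 weight decay 1e-5) with
global gradient-norm clipping at 1.0 — the mean-then-log adversarial term
has unbounded gradients when the discriminator saturates, and clipping is
the minimal stabilizer. Defaults lr 2e-4; the scaled study uses lr_g 8e-4
with a slower discriminator (lr_d 2e-4), which on small models converges
within the epoch budget without the generator collapse seen at higher
rates. After every epoch the mean validation SSIM is computed and the
best-so-far generator weights are kept; training runs at most 200 epochs
by default. Scores at the open-interval boundary are clamped at 1e-7
inside the losses.

## Metrics

SSIM follows the Wang convention (11x11 Gaussian window, σ 1.5,
population covariance, K1/K2 = 0.01/0.03), delegated to scikit-image and
cross-checked against a naive sliding-window oracle. MS-SSIM uses the
canonical 5-scale weights (0.0448, 0.2856, 0.3001, 0.2363, 0.1333) with
2x2 average-pool downsampling, the luminance term only at the coarsest
scale, negative contrast-structure means clamped at zero, and scale count
reduced (weights renormalized) for small images. PSNR returns +inf for
identical images; such values are excluded from table means with a logged
count. The blur score is the Crete-Roffet no-reference estimator with
9-tap averaging kernels: re-blur the image, measure what fraction of
absolute neighbour variation survives (0 = sharp, 1 = blurred), take the
worse axis; BAD is the absolute blur-score difference between a corrected
image and its ground truth. Note the estimator is non-monotonic for
structure at exactly the Nyquist period (a 1-pixel checkerboard), where
re-blurring preserves the alternation pattern; tests use coarser patterns
and vessel images, which behave monotonically. Baselines are bicubic
down/up-sampling (x0.5 then x2), a 5x5 bilateral filter (σ_color 0.1,
σ_spatial 2) and a 5x5 median filter.

## Preprocessing and splits

MAP projection is the per-pixel depth maximum. Angular correction
resamples each line from the sinusoidal galvo positions
x_k = (L/2)·sin(θ_k)/sin(θ_max) (θ uniform) onto a uniform grid by linear
interpolation — it removes only the deterministic distortion and is the
identity below 1 mrad; stochastic jitter is left for the network.
Normalization is per-image min-max (percentile mode clips 0.1/99.9 first);
constant images map to zero. Splitting holds out ceil(0.2·n) test then
ceil(0.1·remainder) validation samples by seeded permutation — the ceiling
rule is adopted because it uniquely reproduces both published held-out
counts (231 and 93 of 1154).

## Scaled study sizes

CPU-sized problem scales are used throughout the automated tests, as the
package's own reference experiment sizes: the 2D end-to-end study trains
on 200 paired 64x64 crops (4 crops from each of 50 scenes, 2 µm reference
raster) with a base-width-8 generator (dense depth 2, growth 4) and a
width-8 discriminator for 25 epochs at fixed seeds; the identity
calibration uses 48 aligned pairs for 14 epochs; the 3D study corrects a
40-plane volume over a 0.55 x 0.5 mm field at the same pixel pitch as
training. The full-size reference configuration (192x192 crops, 7.6 M
parameters) is exercised for construction, parameter counting and forward
contracts, not for training.

## What passing tests do and do not show

The synthetic phantoms share the real data's geometry (pixel pitch, PSF
scale, paired-protocol row alignment, misalignment magnitude) but not its
biological texture: no capillary beds, no depth-dependent fluence decay,
no motion between the two acquisitions, simplified (stationary Gaussian)
noise, and a jitter model invented for want of published statistics.
Passing the end-to-end tests therefore demonstrates that the architecture,
losses and training loop can learn to invert this class of scan-timing
misalignment — not that the shipped defaults reach any particular quality
on in-vivo data. The published in-vivo metric table is not reproducible
without the authors' animal data and is out of scope.

## Degenerate inputs and numerical conventions

Images are row-major, y as rows, 0-based, pixel centers at half-integer
physical coordinates. Constant images: normalize → 0, blur score → 0 with
a warning, SSIM well-defined via the stabilizing constants. Depth-encoding
ties break toward the shallowest plane (argmax convention). Near-empty
en-face planes (range < 1e-6) bypass the network. Checkpoints store raw
float32 weight arrays with the architecture config embedded as JSON.
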