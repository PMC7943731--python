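# Methods

This note records what the package computes, the assumptions behind it,
the tunable parameters that matter, and the choices made where the design
was genuinely open.

## Measurement model

Images are square, real, and normalized to [-1, 1]; vectorization is
row-major everywhere. Three measurement operators are provided.

* **Gaussian compressive** (`build_gaussian_matrix`): M = round(ratio *
  N^2) rows of i.i.d. N(0, 1/M) entries. The 1/M variance makes
  E||Kx||^2 ~ ||x||^2, so the restricted-isometry diagnostic reads on the
  natural scale (an ideal isometry has ratio 1). The undersampling ratio
  M/N^2 is the single knob; the benchmark grid is {0.5, 0.3, 0.1, 0.05}.
* **Ring-array time-domain kernel** (`build_pat_matrix_time`): a pixel at
  distance d from transducer h contributes amplitude 1/(2 pi c) to the
  sample at time t = s*dt when |s*dt - d/c| <= dt/2 — a nearest-bin
  quadrature of the ideal delta kernel, the simplest discretization
  consistent with sampling at t = s*dt. Geometry defaults mirror a
  512-element, 80-mm-diameter, 5-MHz ring (sound speed 1.5 mm/us); a
  proportionally scaled-down desk preset is used in tests. The physical
  kernel may be overdetermined (p*q_s > N^2); only the Gaussian kind is
  required to undersample.
* **Frequency-domain kernel** (`build_pat_matrix_freq`): complex entries
  i c k_n exp(-i k_n d)/d. The wavenumber grid is a configuration list;
  the default spans (0, 2 f_c] in 16 steps with f_c = 5 MHz, covering the
  stated >80% fractional bandwidth of the instrument. Complex adjoints
  use the conjugate transpose and the proxy takes the real part, since
  the reconstruction target is real.

No acoustic wave propagation is simulated: the measurement matrix *is*
the forward model, which is exactly the regime the reconstruction
methods address.

## Phantom generator

`generate_phantom` emulates the visual statistics of small-animal
cross sections: one bright elliptical body outline (a ring), a
configurable number of filled organ blobs at distinct intensities, at
least one thin vessel-like curve (quadratic Bezier, with a deterministic
fallback placement), and a smooth dim background. Features are placed
with a one-pixel separation margin so the bright set decomposes into
exactly 1 + blobs + vessels 8-connected components — a property the test
suite verifies against a brute-force flood fill.

What the generator does **not** emulate: speckle, depth-dependent
fluence, limited-view artifacts, transducer bandpass effects, or the
texture of real tissue. Passing tests therefore demonstrate that the
pipeline is implemented correctly and behaves as expected under the
stated measurement models — not that the trained networks would transfer
to experimental scanner data.

Augmentation applies configured rotations (right angles as exact index
permutations, arbitrary angles by bilinear interpolation with zero
padding), flips (exact involutions), and optional center crops resized
back to the original side. Normalization is the affine map min -> -1,
max -> +1; a constant image maps to zeros with a warning rather than
erroring, so batch pipelines keep running. Splitting is a seeded random
partition with round(fraction * n) training items (1130 images at 0.8
give 904/226).

## Reconstruction networks

The learned pipeline is proxy + network. The proxy stage is the fixed,
non-trained multiplication by K^T ("manually designed" rather than
learned); a trainable dense variant is deliberately out of scope of the
default path. Because K^T K is not a projector, the raw back-projection
has arbitrary scale; the model stores a fixed scalar (calibrated once at
build time from a random probe image) that brings the proxy to O(1)
amplitude before clipping to [-1, 1].

Families (all stride-1, same-padded 3x3 convolutions unless stated):

* `cnn3` — 9x9/5x5/5x5 kernels, 4c/2c/1 channels (c = base_channels,
  desk default 8), ReLU between layers.
* `unet` — depth-3 (desk) encoder/decoder; two 3x3 conv + ReLU per
  level, 2x2 max pooling, 2x2 stride-2 transposed convolutions, skip
  concatenation, channels double per level from base 8; 1x1 output head.
* `resunet` — the same topology with each double-convolution replaced by
  a residual block: conv-BN-ReLU-conv-BN plus identity shortcut (1x1
  convolution when channel counts differ), ReLU after the sum.

Training: l1 loss (mean absolute error), Adam with learning rate 0.005
and batch size 1 (SGD selectable), epochs configurable with desk default
20, everything seeded and bit-reproducible on a fixed platform. One
model is trained per (family, undersampling ratio), following the
method's own protocol. The final layer emits a linear output that is
clamped to [-1, 1] at inference only.

**Initialization.** Weights are He-initialized; the final convolution is
additionally scaled by 0.1 so the network starts near the zero map. With
batch-1 Adam at lr 0.005, a full-scale initial output produces large
early steps that can push every ReLU in the small desk-scale networks
into the dead regime (the net then emits a constant and never recovers);
starting near zero removes that failure mode without touching the
prescribed optimizer settings. Conv biases ahead of batch-norm layers
are retained but redundant (batch norm cancels them).

The engine itself (`deeppat.nn`) is a compact numpy implementation —
im2col convolutions, explicit backward passes, float32 tensors — sized
exactly to these architectures; its backward passes are verified against
numerical directional derivatives in float64.

## TV baseline

`tv_minimize` solves min_x 0.5||Kx - v||^2 + lambda TV(x) with monotone
FISTA: FISTA momentum plus the safeguard that a candidate increasing the
objective is rejected in favor of the previous iterate, so the objective
trace is non-increasing by construction (asserted to 1e-9 slack). The
gradient step backtracks from a power-iteration estimate of ||K||^2. The
TV proximal operator is computed by projected dual ascent (40 inner
iterations by default; step 1/8, the inverse Lipschitz constant of the
discrete Laplacian). Anisotropic TV (separable clip projection, exactly
testable) is the default; isotropic (disc projection) is available.
Forward differences treat the far boundary as zero-gradient, so constant
images have TV exactly 0.

The equality-constrained compressed-sensing program is approached in the
limit lambda -> 0 on noiseless data (verified: an identity operator with
lambda = 1e-8 reproduces its input to 1e-4). `lambda = 5e-3` is the
frozen default for (-1,1)-normalized images under variance-1/M Gaussian
sensing, chosen by a one-time grid search over 1e-4..1e-2 on the
nested-ellipse fixture: it is the smallest grid value whose
reconstruction PSNR is monotone across the full ratio grid
{0.05, 0.1, 0.3, 0.5} (smaller weights lose monotonicity at 0.05-0.1,
larger ones over-smooth less sparse content). The reference run at ratio
0.5 reached 36.39 dB; the regression threshold is frozen at 36.0 dB.

## Quality metrics

SSIM is implemented from first principles as l^a c^b s^gamma with the
standard stabilizing constants c1 = (k1 L)^2, c2 = (k2 L)^2, c3 = c2/2
(defaults a = b = gamma = 1, k1 = 0.01, k2 = 0.03, L = 2 for
(-1,1)-normalized data). Two windows: `global` (one set of moments,
exactly testable against scalar arithmetic, and algebraically equal to
the familiar two-factor form when c3 = c2/2) and the default `gaussian`
(11x11 window, sigma 1.5, edge-replicated filtering, half-window border
excluded from the mean — the convention of common reference
implementations, matched to scikit-image at machine precision in tests).
PSNR uses the data range (2.0) as peak by default, a per-image peak
being ambiguous for signed data; identical images yield +inf, carried as
a sentinel and excluded (but counted) in aggregation rather than capped.
Aggregation reports mean and sample SD (ddof 1, 0 for n = 1) per
(method, ratio) with explicit n.

## Evaluation protocols and problem sizes

The shipped desk-scale protocols (`deeppat.protocols`) fix the study
conditions: 64x64 grid, 200 synthetic phantoms split 80/20, U-Net at
ratio 0.3 for 20 epochs (the main run); a single-image memorization run
(residual U-Net, 800 epochs — a network that cannot drive its training
error to near zero on one image has a defect; this run reaches SSIM >
0.99); a four-way proxy/cnn3/unet/resunet comparison at matched budgets
(two seeds, ratios {0.5, 0.05}, 32x32 grid, 100 phantoms, 20 epochs),
whose family ordering is assessed on per-family means aggregated over
the ratio grid with a one-cross-seed-SD tolerance — at ratio 0.05 alone
every method sits at the SSIM noise floor where ordering carries no
information; and the TV sweep on the nested-ellipse fixture. These sizes
were chosen so any run completes in minutes on a single CPU core; they
are two orders of magnitude below a GPU-scale study, so absolute SSIM /
PSNR values are not comparable with results obtained on real mouse data
at full training budgets — the protocols test orderings, improvements
and solver behavior, which are scale-stable.

## Numerical conventions and degenerate inputs

* Row-major flattening, fixed and documented everywhere.
* Nearest-bin delta discretization with half-width dt/2; a tie at
  exactly dt/2 fires in both adjacent bins (measure-zero in practice).
* RIP ratios are computed as ||K theta||^2 / ||theta||^2 with both norms
  evaluated explicitly, so an exact isometry yields delta-hat = 0
  exactly, not merely to rounding.
* Constant images: TV = 0, normalization maps to zeros with a warning.
* The solver raises (with trace attached) after 10 consecutive objective
  increases; monotone FISTA makes this unreachable except under
  numerical fault.
* ReLU uses subgradient 0 at exactly 0; max-pool ties route gradient to
  the first maximum.

## Known limitations

* The numpy engine is single-image (batch accumulation by looping) and
  CPU-only; it is not a general autodiff framework.
* Desk-scale networks (base 8 channels) under-fit relative to the
  full-width architectures; the plain U-Net in particular converges
  slowly without normalization layers.
* The phantom generator's component-separation guarantee holds for the
  generated set; externally loaded images carry no such structure.
* Bit-for-bit reproducibility is guaranteed per platform/BLAS build, not
  across platforms.
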