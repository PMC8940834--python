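# Methods

`spectdenoise` implements a complete, testable analogue of deep-learning
denoising for low-dose SPECT myocardial perfusion imaging (MPI): synthetic
cardiac phantoms stand in for patients, reduced-dose acquisitions are
simulated by binomial count thinning, a conditional GAN predicts
standard-dose projections from low-dose ones, and reconstruction plus
quantitative/agreement metrics close the loop.

## Simulation model

**Phantom.** The left-ventricular myocardium is modelled as the region
between two confocal half-ellipsoids (outer semi-axes minus a uniform wall
thickness), truncated at the base plane, on a 64³ grid of 6.4 mm isotropic
voxels. Shell activity is uniform; a perfusion defect is a circumferential
sector (angle and axial span in the LV frame) in which activity is
multiplied by `1 − severity`. The defect masks used for carving are stored
with the phantom, so evaluation code has exact ground truth. An optional
ellipsoidal "hot liver" blob and a row-range crop operation mimic the manual
exclusion of hepatic activity from clinical projections.

**Projection.** A parallel-beam line-integral model over a 180° RAO→LPO arc
of 32 evenly spaced views onto a 64×64 detector (6.4 mm pixels). The
projector is voxel-driven: each voxel splats onto at most two adjacent
detector columns with linear-interpolation weights and contributes
`activity × voxel edge length` to the line integral; detector rows copy the
axial index. Each view is a sparse matrix, so the backprojector is the exact
matrix transpose. There is no attenuation, scatter, or depth-dependent
resolution modelling — deliberately, since the clinical protocol being
emulated applies none, and an exact adjoint makes the EM-monotonicity
guarantees of the reconstruction meaningful.

**Counting statistics.** The noiseless projections are rescaled so the total
expected count of a standard-dose study equals a configurable count level,
then each bin receives an independent Poisson draw. The default count level
is 2×10⁵ counts per non-gated 32-view study — the order of magnitude of a
clinical MPI acquisition. This is a declared assumption: acquisition
protocols specify injected activity (≈800 MBq ⁹⁹ᵐTc-sestamibi) and time per
view, not a per-study count total, so the default is the package's choice
and is exposed in configuration.

**Dose reduction.** Low-dose studies are derived from standard-dose counts
by per-bin binomial thinning: every detected event is kept independently
with probability p ∈ {1/2, 1/4, 1/8}. On binned counts a Binomial(n, p)
draw per bin is distribution-identical to Bernoulli selection on the
underlying event list (an explicit event-list adapter exists for
demonstration), and by the Poisson thinning theorem Poisson(λ) bins become
Poisson(pλ). Kept and rejected halves always sum to the parent exactly.
Cardiac gating partitions each bin's counts across 8 gates with a
multinomial draw (uniform weights by default), independent of thinning.

## Denoising network

The generator is a six-level U-Net over single 64×64 projection views
(each of a study's 32 views is one training sample): 4×4 stride-2
convolutions with encoder filters (64, 128, 256, 512, 512, 512) down to a
1×1 bottleneck; batch normalization in encoder blocks 2–4; LeakyReLU(0.2)
in encoder blocks 1–5 and ReLU in block 6; stride-2 transposed-convolution
decoder blocks (512, 512, 256, 128, 64, 1) with skip concatenations into
decoders 1–5, dropout (rate 0.5) in decoder 1, ReLU after each
concatenation and a sigmoid output; no pooling anywhere. The discriminator
is conditional: the low-dose view and a candidate standard-dose view are
concatenated channel-wise and passed through four 4×4 conv blocks (filters
48, 96, 192, 384; strides 2, 2, 2, 1; conv → batch-norm → LeakyReLU(0.2)),
then a 1×1 single-filter conv, batch-norm and sigmoid, giving an 8×8 patch
probability map.

Training alternates discriminator steps (binary cross-entropy on real/fake
pairs) with generator steps minimizing `1·BCE(D(x, G(x)), 1) + 100·MSE`,
using Adam at learning rate 0.001 for ~50 epochs, batch size 8. Views are
normalized by one global constant — the maximum reference-view count of the
training set — stored with the model; the sigmoid output requires targets
in [0, 1], and predictions are inverse-scaled to counts. Separate models
are trained per dose level.

Choices the architecture description leaves open, fixed here: batch
normalization is applied in all four discriminator conv blocks (a flag
exposes the first-block variant); the final decoder applies no batch-norm
between the transposed convolution and the sigmoid, since normalizing the
output head would fix its distribution regardless of input; padding is
"same"; weights are initialized N(0, 0.02); no label smoothing.

The whole network stack is implemented directly in NumPy (im2col/col2im
convolutions over BLAS matrix products, manual backpropagation, Adam), in
float32. This keeps training bit-reproducible for a fixed seed on a given
platform, which the test suite relies on.

## Reconstruction

OSEM with interleaved angular subsets (default 8 iterations, 2 subsets),
multiplicative EM updates with per-subset sensitivity normalization; voxels
with zero sensitivity are frozen at zero rather than divided by zero. With
one subset this is MLEM: the Poisson log-likelihood is non-decreasing and
total reprojected counts equal total measured counts after every full
iteration — both properties hold exactly because the backprojector is the
projector's true adjoint, and both are tested. Post-smoothing is a radially
symmetric Butterworth filter `H(f) = 1/(1 + (f/f_c)^{2n})` applied in the
frequency domain (default order 10, cutoff 0.45). The cutoff is interpreted
as a fraction of the Nyquist frequency and the squared-magnitude convention
is used — the dominant convention in nuclear cardiology — but both the form
and units are configuration-exposed rather than hard-wired, since a bare
"cutoff = 0.45" is ambiguous across vendors. Reorientation to the
short-axis frame is a rigid rotation (azimuth about the scanner axis, then
elevation), with vertical/horizontal long-axis stacks obtained by axis
permutation; phantoms know their ground-truth LV axis, so no automatic axis
detection is attempted.

## Evaluation

RMSE, PSNR and SSIM are computed pairwise against the standard-dose
reference. PSNR defaults to `20 log₁₀(peak/RMSE)` with `peak` the maximum
of the test data; a `peak/MSE` variant is selectable because that form
appears verbatim in some reports despite being dimensionally inconsistent —
since the two differ by a monotone transform of MSE, comparisons and
percent changes computed on published means are unaffected by the choice.
SSIM uses a single global window with absolute constants C₁ = 0.01,
C₂ = 0.02 (no sliding window, no dynamic-range rescaling of the constants).
Bland–Altman agreement reports bias and mean ± 1.96 sd limits (sample sd)
plus a paired t-test; on 10⁴ simulated Gaussian pairs the limits cover ≈95%
of differences, which the suite verifies.

The 17-segment summed score is a transparent surrogate for proprietary
clinical scoring software, not a reproduction of it: AHA polar segments
(basal/mid 6×60° sectors, apical 4×90°, apex cap) are sampled on the
short-axis volume, per-segment mean uptake is expressed as a fraction of
the maximal segment uptake, and scored 0–4 at thresholds 70/50/30/10 %.

## Problem sizes and scaled-down study conditions

The clinical study behind this design used 295 training and 35 test
patients and a GPU; this package's tests and the acceptance script run the
same pipeline at desk scale, chosen once as follows: cohorts of 4 training
phantoms (128 view pairs) and 2–4 test phantoms, 2×10⁵ counts per study,
50 training epochs, and a width-reduced network (filter counts scaled by
1/8, identical depth, topology, losses and optimizer). The full-width
architecture is constructed and verified shape-by-shape in the tests; the
width reduction only lowers capacity, not structure. Under these conditions
the package reproduces the qualitative findings: predicted standard-dose
views beat their low-dose inputs in mean PSNR at every dose level, and
prediction quality degrades monotonically from half to eighth dose. Because
the toy GAN is stochastic and small, the per-seed margin at half dose is a
few dB; the dose-ordering property is therefore assessed on seed-averaged
means over three seeds.

What the synthetic data do not emulate: attenuation and scatter (and hence
their artifacts), depth-dependent collimator response, patient motion,
anatomical variability beyond ellipsoid jitter, and realistic extra-cardiac
background. Passing tests demonstrate the correctness of the pipeline's
operations and the reproducibility of the denoising effect under the stated
noise model — not clinical performance.

## Numerical notes

- Thinning/gating conservation identities are integer-exact, not
  approximate; tests assert bit equality.
- OSEM ratio updates define 0/0 = 0 (bins with zero predicted and zero
  measured counts), and the log-likelihood omits constant log(y!) terms.
- The Butterworth filter preserves the DC component exactly; filtered
  reconstructions are clipped at zero to maintain the nonnegativity
  invariant of activity volumes.
- All randomness flows from one master seed through named substreams
  (phantom, poisson, thinning, gating, training), so any stage can be
  re-run in isolation; derived seeds stay below 2³¹.
- Training aborts with a diagnostic if the generator loss becomes
  non-finite rather than silently continuing.
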