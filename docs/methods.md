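# Methods

This note records the model, the conventions, and the design choices made
where the design was genuinely open, in enough detail to reimplement the
package from it.

## Problem setting and assumptions

The package fuses *registered, single-slice* grayscale image pairs: an
anatomical CT slice (natively 512×512, Hounsfield units) and a functional
PET slice (natively 128×128, tracer uptake). Registration is assumed done
upstream; no module deforms images. PET is resampled to the CT grid
(bilinear by default, bicubic selectable) and both slices are min-max
normalized **per image** — CT and PET live on unrelated physical scales,
so a joint normalization would be meaningless. A constant image normalizes
to all zeros (documented convention avoiding 0/0). Coordinates are
row-major, origin top-left, pixel-center aligned for all resampling.

## Network

Both modalities pass through one encoder function with a single shared
parameter set (`untied=true` duplicates the encoder parameters for
ablation; the siamese tying is the method's defining property and the
default).

- **Stem**: one 3×3 convolution (1 → 16 channels), ReLU, SAME padding.
  The kernel size is fixed by the method; the width (16) is a default.
- **Channel coupling**: per-channel gate
  σ(MLP(AvgPool(F)) + MLP(MaxPool(F))), where the two-layer MLP
  (bottleneck = channels / 4, ReLU) is shared between the avg- and
  max-pooled descriptors. The gate is applied multiplicatively,
  F′ = g ⊙ F: the gate itself is a per-channel scalar, and forwarding it
  bare would discard all spatial content that the next block convolves.
- **Spatial pyramid coupling**: an inner 3×3 convolution, adaptive average
  pooling onto the four fixed grids (16, 4, 2, 1), a per-scale 3×3
  convolution (16 → 8 channels, ReLU), bilinear upsampling of every level
  back to input resolution, channel concatenation (4 × 8 = 32 channels).
  The resolution-matching mechanism (bilinear, before concatenation) is an
  implementation choice; the pooling grids are fixed by the method.
  Inputs smaller than the largest grid raise an error naming the remedy
  (a smaller `spp_scales`).
- **Branch output**: channel concatenation of {F′, F″, original image} =
  16 + 32 + 1 = 49 channels. "Superimposition" is read as concatenation
  because the three blocks have different channel counts, so additive
  superposition is ill-typed without extra projections.
- **Cross-correlation fusion** (parameter-free): for displacement
  d ∈ {−o·r, …, 0, …, o·r}² in steps of the stride o = 3 (default radius
  r = 1, i.e. 9 channels), the response at each site is the sum over the
  3×3 patch of the channel-averaged product of the CT stack with the PET
  stack shifted by d, zero-padded (SAME). The patch size and the bounded
  displacement window are implementation decisions — an unbounded
  all-pairs correlation is quadratic in image area and produces a 4-D
  volume with no decodable reduction; r is configurable, and r large
  enough recovers the global correlation on small inputs (used by the
  oracle tests). The stride o = 3 is fixed by the method.
- **Decoder**: three transposed convolutions (9 → 16 → 16 → 1, 3×3,
  stride 1, SAME geometry), ReLU between stages, sigmoid output so the
  fused slice lies in [0, 1] like its normalized sources.

Every stage preserves the spatial size, so the fused slice has the source
resolution for any input whose sides are ≥ 16 (the largest pyramid grid).

## Objective

L = (1 − SSIM(x_ct, y)) + (1 − SSIM(x_pet, y)) + λ·Σ|ω|, with
C1 = (k1·L)², C2 = (k2·L)², k1 = 0.01, k2 = 0.03, L = 1 for normalized
images. SSIM uses **whole-image moments by default** (population
variances); a windowed mode (11×11 Gaussian, σ = 1.5, valid support,
averaged) is provided, as local SSIM is the more common training signal —
both modes are tested and differentiable. Σ|ω| is the L1 norm of all
network weights; λ (default 1e-4) keeps the penalty from dominating the
two bounded SSIM terms for a realistically sized network, and λ = 1
recovers the unweighted sum. An unweighted image-domain reading of the
penalty was considered and rejected: the objective's own description ties
it to weight regularization ("prevent overfitting"), and an image-domain
L1 would duplicate the SSIM terms' role.

## Optimization

Xavier/Glorot-uniform weights (variance 2/(fan_in+fan_out)), zero biases,
seeded. AdaGrad with per-parameter accumulated squared gradients,
ε = 1e-8, and **accumulator initialized at 0.1** (the TensorFlow 1.x
convention): starting the accumulator at zero makes the first update a
coordinated ±lr jump on every weight, which can saturate the output
sigmoid into a dead constant-output state. Defaults: learning rate 0.01,
batch 4 (whole slices; the network is fully convolutional), epochs
configurable. A non-finite batch loss aborts with the offending batch
named.

The split protocol shuffles once (seeded), cuts the dataset into five
chunks, and rotates which chunk validates: 4:1 train/validation, five
disjoint rotations covering every pair exactly once (672/168 at n = 840).

## Synthetic phantoms

The generator emulates the *statistical structure* of a registered
clinical pair, not its physics: a body ellipse (intensity 0.55), two
darker lung fields (0.15), a bright spine (0.95) and six rib
cross-sections (0.90) on the unit square, all jittered ±10% per seed;
additive Gaussian texture (σ = 0.02) and clipping to [0, 1] give the
CT channel its fine gradient. The PET channel shares the same seeded
geometry: a smooth low background following the body outline plus
Gaussian-profile hotspots (peaks 0.7–1.0, σ = radius/2, radii scaling
with the grid: 3–7 px at 128) placed inside the lung fields by rejection
sampling, blurred (σ = 2 px) and block-averaged down by the integer
CT/PET factor (4 by default, mirroring 512/128). The lesion support disks
are returned as a full-resolution mask.

Defaults are 128×128 CT / 32×32 PET; tests run mostly at 64 and 32 px and
training demonstrations use 40–50 pairs — sizes chosen so the whole suite
runs in minutes while every structural property (modality contrast,
registration, blur monotonicity) is scale-independent. What the phantoms
do **not** model: attenuation physics, reconstruction artifacts, 3-D
structure, respiratory misregistration, or the intensity statistics of
real FDG uptake. Passing tests therefore demonstrate the *mechanics* of
the method — not clinical fusion quality on real scans, which requires
the real registered data and longer training.

## Metrics

- Mean and population standard deviation of the fused slice.
- Average gradient: forward differences on the interior grid (last
  row/column excluded), per-pixel magnitude √((Δx² + Δy²)/2).
- Entropy: 256 uniform bins on [0, 1], natural log, empty bins contribute 0.
- RMSE: reported per source and averaged over the two.
- NMI = 2·[H(I₁,F)/(H(I₁)+H(F)) + H(I₂,F)/(H(I₂)+H(F))] with 256-bin
  marginal and 256×256 joint histograms, natural log; bounded in [2, 4]
  (each ratio is ½ for identical images, → 1 for independent ones).
  Degenerate zero-entropy operands pin their ratio at ½. The plug-in
  joint-entropy estimator is biased low for small images (~0.2 NMI units
  at 256²), so the independence-limit test runs at 512².
- VIF: pixel-domain visual information fidelity, scalar Gaussian scale
  mixture, four dyadic scales, σ_nsq = 2, Gaussian windows of size
  2^(4−s+1)+1 with σ = size/5, edge-replicated boundaries (so 32×32
  validation slices remain scoreable; the classic valid-region filtering
  needs ≥ 35 px). Reported per source and averaged.

## Numerical choices and degenerate inputs

Float64 throughout. Ties in the global max pool take the first index.
Bilinear resampling clamps source coordinates at the borders (edge
replication). Constant images: normalization → zeros; entropy → 0;
NMI ratio → ½; VIF with a constant *reference* is undefined and raises.
SSIM of two constants equals its luminance term only (variances vanish).
The identity fixtures (ct = pet = fused) pin all conventions: loss 0,
RMSE 0, NMI 2, VIF 1.

## Fixture-scale demonstrations

Two training demonstrations back the test suite. (1) Usefulness: 50
phantom pairs at 64×64, 40 train / 10 held out; after two epochs the
held-out mean SSIM(ct,·)+SSIM(pet,·) of the trained model exceeds the
Xavier-initialized model's for every seed tested. (2) Convergence: on the
ct = pet fixture (32×32, λ = 0) a deliberately tiny configuration — stem
4, pyramid branches 2, decoder widths (8, 8), MLP bottleneck 2,
displacement radius 2 — reaches total loss < 0.1 within 200 AdaGrad steps
at learning rate 0.2. The tiny width keeps the per-step cost trivial and
the larger displacement window gives the decoder a richer parameter-free
input; both are configuration choices documented here, not changes to the
package defaults (stem 16, radius 1, lr 0.01).

## Known limitations

- Global-moment SSIM is an unusual training signal; it optimizes slice
  statistics, and fine edge structure converges slowly (the windowed mode
  is provided but is not the default objective).
- The correlation layer discards per-channel detail by design (channel
  averaging); reconstruction sharpness is bounded by what the displaced
  patch products retain.
- No GPU path; the numpy engine is single-threaded apart from BLAS.
- Single-slice only; no SUV calibration, windowing presets, or 3-D
  context.
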