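# Methods

## Model

The reconstruction model is an unrolled cascade: *m* repetitions of
CNN refinement in the image domain followed by soft data consistency (DC)
in k-space. Inputs are multi-coil complex k-space arrays `[c, h, w]` with
the phase-encoding direction on the last axis; all Fourier transforms are
centred (shift → transform → shift) and orthonormal, so Parseval holds
exactly and undersampling masks act on the middle of the array.

Per cascade:

1. coil reduction `I_red = Σ_i F⁻¹(k_i) · conj(S_i)` to a single complex
   image, represented as two real channels (real, imaginary);
2. CNN refinement of `I_red` (or, with dense connections, of the
   concatenation `[I_red^k, I_red^{k−1}, …, I_red^1]`, newest first, giving
   2·k input channels at cascade k);
3. coil expansion `I_rec ∘ S_i`, Fourier transform, and DC:
   `(k_u + λ k_p)/(1 + λ)` on sampled lines, `k_p` elsewhere.

λ is a learnable scalar per cascade (not shared — per-cascade parameters
strictly generalise sharing), initialised to 0.01. Sub-network weights are
likewise not shared across cascades. The final output is the
root-sum-of-squares magnitude of the coil images of the last cascade's
data-consistent k-space.

Coil sensitivities are estimated once per input by a separate network of
the same architecture at half the base width: the fully sampled centre
block of k-space is inverse-transformed per coil, each coil image is
refined with the coil index mapped onto the batch axis (so any coil count
works with one built model), and the maps are normalised to pixelwise unit
energy `Σ_i conj(S_i) S_i = 1`. Pixels of (near) zero total energy are
regularised by an ε = 1e−12 in the division and come out near zero rather
than NaN.

### Sub-networks

Both sub-network kinds share a U-Net skeleton: an encoder with 2×2 average
pooling between resolutions, a decoder with nearest-neighbour upsampling,
skip concatenations, channel counts doubling per level, instance
normalisation and SiLU throughout. Inputs are reflect-padded to a multiple
of `2^(depth−1)` and cropped back, so any rectangular size is accepted.

* **UNet** (baseline): two conv–norm–SiLU stages per level.
* **ResXUNet**: aggregated residual bottleneck blocks — 1×1 conv, grouped
  3×3 conv (cardinality clipped to the gcd with the channel count), 1×1
  conv, with squeeze-and-excitation applied at the end of the branch
  before the identity addition and no activation after the addition, so a
  zeroed branch is exactly the identity.

The sub-network output is a **residual correction**: the head's 2-channel
output is added to the first two channels of the network input (the most
recent coil-reduced image). This follows the residual-refinement
convention of DC-cascade models; without it an untrained cascade outputs
near-zero images and must first learn an identity mapping, which at
desk-scale step budgets visibly stalls early training.

**Interconnections** carry the final feature map at every resolution from
one sub-network to the next, where they are concatenated onto the encoder
features at the matching resolution. Decoder-side feature maps are the
default source (the bottom resolution uses the bottleneck output); an
encoder-side source is selectable in `SubnetConfig` since the choice is a
genuinely open design point. The first cascade receives no packet.

### Presets and parameter budget

Five presets map to the ablation variants: `reference` (UNet, no
extensions), `dense`, `resxunet`, `interconnections`, and `dircn` (all
three extensions). Default cascade count is m = 12. Full-scale widths are
chosen per architecture so every variant lands near a common budget of
roughly 45 M learnable parameters (UNet base 34, ResXUNet base 52 — the
grouped convolutions make ResX blocks lighter per channel); the `tiny`
presets (m = 2, depth 3, 8 base channels, cardinality 4, SE reduction 4)
are the desk-scale configuration used throughout the tests.

## Undersampling masks

Masks are deterministic binary patterns over phase-encoding lines: a
contiguous centre of `round(center_fraction · n_ky)` lines (8% at R = 4,
4% at R = 8), placed from `floor((n_ky − count)/2)`, plus every R-th line
outside it starting at `offset` (default 0). An `exact_rate` dialect
widens the equidistant spacing so the realised rate approaches `n_ky/R`,
matching leaderboard-style masks; the literal every-R-th-line scheme is
the default. `mask_stats` reports the conventional effective acceleration
`n_ky / sampled_lines`. During training each slice draws R ∈ {4, 8} with
equal probability from the run's seeded RNG; evaluation uses fixed masks
per volume.

## Loss and metrics

Training loss: `(1 − SSIM) + mean|pred − ref|`, equally weighted, with the
data range taken as the maximum of the reference slice. SSIM uses an
11×11 Gaussian window (σ = 1.5, truncated at radius 5), K1 = 0.01,
K2 = 0.03, population covariance normalisation, averaged over the interior
where the window fits entirely — the convention of the public multi-coil
reconstruction benchmarks, and the same in the differentiable and numpy
implementations (they agree to ~1e−10). At evaluation, SSIM is the mean
over slices with the volume-level data range; NMSE and PSNR are per
volume, PSNR capped at 100 dB for exact matches. Aggregates are unweighted
means over volumes.

## Training schedule

Adam with AMSGrad, initial learning rate 2e−3, decayed ×0.1 every 60th
iteration, batch size one, 120 iterations of 10,000 randomly drawn slices
with 4,000 fixed validation slices — these full-scale defaults are kept in
`TrainConfig`; desk-scale runs shrink `n_iterations`/`slices_per_iteration`
through the same config (the bundled smoke experiment uses 4 × 50 steps).
No data augmentation. Training aborts with a diagnostic on a non-finite
loss. Per-step logs record the loss, learning rate and the mean absolute
parameter gradient per cascade; the per-cascade profile is the tool for
checking that gradient flow reaches the earliest cascades.

## Synthetic data

The generator emulates the statistical structure the method assumes, not
anatomy: piecewise-constant ellipse composites (one large background
ellipse plus 2–5 internal structures with signed amplitudes) under a
smooth unit-magnitude linear phase field; per-coil smooth complex
sensitivity lobes (Gaussian magnitude bumps spread around the field of
view, per-coil linear phase, normalised to unit energy); k-space per coil
as `F(S_i ∘ x)` plus i.i.d. complex Gaussian noise of per-component
standard deviation σ (default 0.01 against image amplitudes of order 1,
i.e. ≈1% noise). Phantoms are generated with 16 samples of frequency
oversampling along the width, cropped quadratically in the image domain
and re-transformed, exercising the same preprocessing path as real raw
data. The stored ground truth is the RSS of the noiseless cropped coil
images, so with σ = 0 and a full mask the reconstruction problem is
exactly solvable — and undersampled zero-filled RSS is strictly worse,
which is the signal the learner removes. Defaults (64×64, 4 coils) are
sized for CPU training.

What passing tests on this generator do *not* show: robustness to real
anatomy and contrast physics, coil noise correlation, scanner-specific
artefacts, or performance at clinical matrix sizes; those require real
multi-coil raw data.

## Numerical choices

* float32 parameters and activations; float64 in metric computations and
  gradient checks.
* Sensitivity normalisation and the tensor RSS add ε = 1e−12 under the
  square root to avoid undefined gradients at exactly zero.
* Centre-crop offsets use the floor convention `floor((dim − target)/2)`.
* Convolutions are stride-1 with 'same' zero padding; down/upsampling is
  average pooling / nearest-neighbour so all shape changes are exact
  factors of two after reflect padding.
* Model construction draws initial weights (uniform ±1/√fan_in) from a
  seeded RNG; building, training and evaluation are bit-reproducible given
  the seed on CPU.

## Known limitations

* The engine is CPU-bound and sized for desk-scale configs; full-scale
  (45 M parameter, m = 12) models build and count correctly but training
  them is impractical without an accelerator-backed framework.
* Only Cartesian line-wise masks are implemented (no Poisson/2-D masks),
  no partial-Fourier or off-resonance handling, and no k-space-domain
  sub-networks.
* `batch_size > 1` is gradient accumulation over slices, not true
  batching.
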