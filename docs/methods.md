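# Methods

## Problem setting

High-speed volumetric two-photon calcium imaging with a resonant varifocal
(TAG) lens sweeps the focus axially at hundreds of kHz, producing volumes of
hundreds of z-slices at sub-micrometre spacing while the voxel dwell time
drops to tens of nanoseconds.  The photon budget per voxel is then so small
that raw frames are shot-noise dominated.  Because the axial point-spread
function (PSF) extends over many slice spacings (≈5 µm FWHM against ≈0.25 µm
spacing in the regime this package targets), *adjacent z-slices observe
essentially the same scene under independent photon noise*.  That redundancy
is the entire basis of the method: two adjacent slices form a valid
Noise2Noise input/target pair, so a denoiser can be trained on a recording
with no clean ground truth and no information mixed across time points.

## Self-supervised pairing

For one volume with Z slices, slices (2k, 2k+1) form pair k; the even slices
are stacked into a 3D input stack and the odd slices into a 3D target stack
(`pairing.make_stack_pair`).  Independently per pair, input and target roles
are exchanged with probability 0.5, re-drawn every epoch, which removes any
systematic asymmetry of the even/odd convention and enriches the regression
with differently paired noise instances.  Pairs are non-overlapping — each
slice is used exactly once per volume — so input and target never share a
voxel (the anti-leakage property that makes the objective a Noise2Noise
regression rather than an autoencoder).  An odd trailing slice is dropped
from training and neighbour-filled at reconstruction.

A `pairing="temporal"` training mode pairs whole volumes at adjacent time
points instead.  It exists only as the comparison baseline: temporal pairing
regresses each frame toward its neighbours, which attenuates single-frame
transients — exactly the artifact the adjacent-z pairing is designed to
avoid, and the package's tests measure that attenuation directly.

## Network and objective

The denoiser is a 3D U-Net-family encoder–decoder (`denoiser`, `nn`):
per resolution level two 3×3×3 convolutions + ReLU, 2×2×2 max pooling on the
way down, nearest-neighbour upsampling and skip concatenation on the way up,
and a final 1×1×1 convolution to one channel with no output nonlinearity.
Channel width doubles per level.  The published architecture's exact layer
table is not available, so the family is parameterised by `levels` and
`base_channels`; the reference configuration used throughout the tests is
levels=2 with 16 base channels (76 609 parameters by closed-form count).

The loss is the average of the L1 and L2 norms of the output−target
difference, `0.5·mean|d| + 0.5·mean d²` — L1 for outlier robustness, L2 for
smooth convergence.  Optimisation is Adam at learning rate 1e-3.  The
network and its exact gradients are implemented directly in NumPy
(single-sample, channels-first float32); convolutions are evaluated as one
GEMM per kernel offset, which on a single CPU core is severalfold faster
than im2col because it avoids the large gather copy.

Intensities are normalised to zero mean / unit variance with statistics of
the whole recording, captured once in `norm_stats` and inverted exactly at
inference.  Training samples are one time-point volume's stack pair (pairs
never cross time points); one model is trained per recording with all
volumes as i.i.d. samples.  Random (16, 32, 32) crops bound the per-step
cost; 20 epochs suffice on the reference phantom (the training log is
recorded per epoch).  Inference passes each full-depth volume through the
fully convolutional network (reflective padding to the 2^(levels−1)
divisibility constraint), un-normalises, and clamps at zero; a `paired`
mode that denoises even/odd stacks separately and interleaves them is also
provided.  Frame t of the output depends on frame t of the input alone — the
no-temporal-mixing guarantee is asserted in the tests as exact
frame-permutation equivalence.

**Convergence behaviour.** Because the target is itself noisy, the training
loss converges toward a positive noise floor, not to zero.  On the reference
phantom the floor — computed independently as the loss between the noise-free
expected observation and the noisy target stacks — is ≈0.54 in normalised
units, and the trained model's final epoch loss must land within 15 % above
it (and strictly above half of it).  Expecting the loss to halve between the
first and last epoch would not be meaningful here: with zero-initialised
biases the network starts near the data mean and the epoch-1 average is
already close to the floor.

## Synthetic phantom

`synthetic` generates the full study conditions with ground truth:

- **Geometry.** Parallel tube dendrites (width 2.5 µm) in the upper z range
  converging toward spherical somata (radius 2 µm) deeper in the volume,
  labelled pre-blur so ROI masks are unambiguous.  Dendrite tubes carry a
  static sinusoidal intensity modulation along their axis (amplitude 0.3)
  emulating varicosities; perfectly uniform parallel tubes would make
  x-translation unobservable (the aperture problem) and motion recovery
  ill-posed.
- **Dynamics.** A population Poisson event train (2 Hz during the active
  period) drives every dendrite through a causal mono-exponential kernel
  (τ_fast = 0.15 s, peak at the event frame) with per-dendrite amplitude
  jitter; each soma receives a slow (τ_slow = 0.6 s) response to the same
  events with a per-soma gain, and a configurable fraction of somata get the
  *negated* response — reproducing the dendrite-coherent / soma-divergent
  population structure, including negative-going somata.  Traces are exactly
  zero during the rest window so ΔF/F baselines are well defined; event
  counts follow Poisson statistics over the active duration.
- **Optics.** Separable Gaussian PSF, FWHM 5 µm axial / 0.7 µm lateral at
  0.25 µm z-spacing and 1 µm pixels (the `dxy_um` field); with 20× axial
  oversampling the median adjacent-slice correlation of the clean scene
  exceeds 0.99 — the redundancy premise.
- **Corruption**, in physical acquisition order: (1) per-slice acquisition
  delay (linear sweep by default, sinusoidal lens phase optional) applied by
  resampling each voxel at its delayed time; (2) per-frame lateral
  translation as a bounded Gaussian random walk; (3) Poisson photon counts
  at `baseline_photons` expected photons per unit intensity (4 in the
  reference phantom, putting raw volumes in the few-dB SNR regime) plus
  Gaussian read noise (SD 0.5 counts, a standard PMT counting model).  The
  dataset also stores the noise-free *expected* observation, so tests can
  isolate the stochastic residual; the median adjacent-slice correlation of
  that residual stays below 0.05 — the noise-independence premise.  (The
  median is the right summary: a single-pair correlation estimate over a few
  thousand heteroscedastic samples fluctuates by several hundredths even for
  truly independent noise.)

The reference phantom (16 volumes of 32×64×64 voxels) is deliberately
desk-scale: every claim is tested as a property (gain thresholds, peak-frame
fidelity, monotone correlation decline) rather than by reproducing in vivo
magnitudes.  What the phantom does not model: depth-dependent scattering and
attenuation, axial motion, photobleaching, non-Gaussian PSF tails, and
sub-Poisson PMT statistics; passing tests therefore demonstrate the
correctness and self-consistency of the algorithms under the stated
assumptions, not their performance on any specific animal preparation.

## Temporal-delay correction

The voxel at slice z is acquired at times n·T + d_z (T the volume period,
d_z from the delay map).  `temporal_correct` resamples each voxel's series at
the reference times (n + φ)·T by linear interpolation between its two
bracketing observations, clamping to the nearest observation at the
boundaries.  The operation is exact for series linear in time (interior
frames), which the test suite checks at machine precision.

## Motion correction

Lateral tissue motion is modelled as a pure translation (t_x, t_y) — no
rotation, shear or scale.  The translation is estimated by maximising a
Mattes-style mutual information metric (joint histogram with linear
partial-volume binning, 50 bins, so the metric varies smoothly under
sub-pixel shifts; constant images are assigned MI 0) with a one-plus-one
evolution strategy: mutate the current best by an isotropic Gaussian step of
the current radius, accept improvements (radius × 1.05), reject otherwise
(radius × 0.98), stop at radius 1.5e-3 or the iteration cap.  The accepted
metric log is non-decreasing by construction and exposed for audit.

A flat single-start search is not reliable when the displacement exceeds the
basin of the MI peak, so the strategy runs inside a three-stage coarse-to-
fine Gaussian smoothing pyramid (σ = 4, 2, 0 pixels; the stage radius starts
at max(initial radius, σ)) — the standard construction in intensity-based
registration toolkits.  With it, injected random-walk motion (step SD 1 px)
is recovered with mean absolute residual well under 0.5 px at 8 expected
photons, and the estimate agrees with an independent ITK-based
implementation to sub-pixel accuracy.  Frame 0 is the reference; every
other frame is registered to it and resampled bilinearly (zero fill), with
the convention that the estimate reports the frame's *motion* (its negation
aligns).  The similarity is evaluated on the z-mean projection by default
(`slice_mode="mean_mi"` averages per-slice MI instead).

Structural-to-functional co-registration (`coregister_structural`) mean-
projects the first seconds of the functional recording, resamples the
structural stack to the functional z-grid via the declared dz ratio, and
runs the same translation-only search under normalised mutual information
(H(A)+H(B))/H(A,B).

## Trace analysis and metrics

ROI traces are integrated densities over label masks; ΔF/F is normalised to
the mean of a quiescent rest window, so it is invariant under global
intensity rescaling.  Somatic responses are classified three ways at
|ΔF/F| = 0.2 using the mean over the stimulation window (boundary values are
neutral; a peak statistic is available).  ROI depth is the intensity-
weighted z-centroid of the mask; `pairwise_correlation` bins ΔF/F traces by
depth and reports the full Pearson matrix and its off-diagonal mean per bin,
excluding (not zero-filling) undefined pairs from constant traces.

Image quality: PCC over flattened volumes; PSNR = 10·log10(peak²/MSE) with
peak defaulting to the reference maximum; SNR defined operationally as the
foreground energy ratio 10·log10(Σ ref²/Σ (signal−ref)²) against a reference
image — ground truth on synthetic data, or a centred 60-frame boxcar average
(`moving_average_reference`) on real recordings.  dB differences convert to
percent as 100·10^(ΔdB/10) with an explicit rounding rule (truncation or
nearest ten), matching how such gains are conventionally quoted.

**Spike-peak fidelity** is measured over *isolated* ground-truth events
(no other event within ±2 frames): for each, the argmax of the denoised ΔF/F
trace over the ±2-frame window must equal that of the ground-truth trace.
When two events land 1–2 frames apart even the ground-truth trace has a
single merged peak, so a per-event peak frame is not defined; near-tied
double peaks would flip on amplitude jitter regardless of denoising quality.

## Numerical and design choices

- Canonical layout (t, z, y, x), z increasing with depth; volumes stored
  t-major on disk as multi-page TIFF (uint16 or float32); acquisition
  metadata in YAML side-cars, never TIFF tags.
- The optimizer, learning rate and epoch count of the original training are
  not published; Adam at 1e-3 with per-volume samples and an explicit seed
  is the package default, with everything exposed in `TrainingConfig`.
- Depth divisibility at inference is met by reflective padding then
  cropping, avoiding zero-padding edge artifacts.
- Undefined quantities fail loudly: PCC of a constant image, SNR with a
  zero-energy reference, ΔF/F with a non-positive baseline and inference
  from an untrained model all raise typed errors rather than returning
  sentinels; identical-input PSNR/SNR return +inf.
- All stochastic components (phantom, pairing swaps, training order and
  crops, optimizer mutations) take explicit integer seeds and are
  reproducible bit-for-bit on a fixed platform.

## Known limitations

- The NumPy network trains on CPU at desk scale (tens of epochs on
  ~16-volume recordings in minutes); it is not a GPU-scale training stack.
- Registration covers lateral translation only — no rotation, scale or
  non-rigid deformation, and no axial motion.
- The temporal-delay model assumes delays constant within a recording and
  shorter than one volume period.
- Transferring trained weights across recordings is mechanically supported
  (`save_model`/`load_model`) but not validated as a workflow.
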