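# tagspark

Self-supervised denoising and analysis for high-speed volumetric two-photon
calcium imaging with dense axial sampling.

## The problem

Fast volumetric two-photon microscopes that sweep the focus with a resonant
varifocal (TAG) lens record hundreds of z-slices per volume at video rate —
but the voxel dwell time collapses to tens of nanoseconds, so each voxel
collects only a handful of photons and the raw data are dominated by shot
noise.  Clean ground truth for supervised denoising does not exist for fast
functional recordings, and denoisers that exploit *temporal* redundancy mix
information across time points, distorting exactly the fast calcium
transients one wants to measure.

This package implements the alternative: when the axial slice spacing is far
below the axial PSF extent (≈0.25 µm spacing against a ≈5 µm PSF), adjacent
z-slices are two independently noisy observations of the same scene.  They
form valid Noise2Noise input/target pairs, so a denoiser can be trained on
the recording itself — *within* each time point, never across them.

## The method

For each volume, even z-slices are stacked as the network input and odd
slices as the target (roles swapped per pair with probability 0.5 each
epoch).  A 3D encoder–decoder network f_θ (U-Net family: 3×3×3 convolutions,
2×2×2 pooling, skip connections) is trained to minimise

    argmin_θ  Σ_i  L( f_θ(x̂_i), ŷ_i ),      L(a, b) = ½·mean|a−b| + ½·mean(a−b)²

where (x̂_i, ŷ_i) are the paired noisy stacks.  Because the noise in the
target is independent of the input, the regression converges toward the
clean scene; because pairs never cross time points, frame t of the output is
a function of frame t of the input alone.  The network and its gradients are
implemented directly in NumPy and train on a single CPU core at desk scale.

Around the denoiser the package provides the full measurement pipeline:

- `tagspark.synthetic` — a Purkinje-cell-like phantom generator (dendrite
  tubes over somata, shared fast dendritic events, slow/negative somatic
  responses, Poisson + read noise, per-slice acquisition delays, lateral
  drift) with complete ground truth;
- `tagspark.preprocessing` — per-voxel temporal-delay correction and
  translation-only motion correction by Mattes-style mutual information with
  a one-plus-one evolution strategy in a coarse-to-fine pyramid, plus
  structural-to-functional co-registration under normalised MI;
- `tagspark.analysis_metrics` — ROI integrated-density traces, ΔF/F against
  a rest-state baseline, ±0.2 three-way response classification,
  depth-binned pairwise trace correlation, PCC / PSNR / SNR and dB↔percent
  conversion;
- `tagspark.pipeline` / the `tagspark` CLI — config-driven
  simulate → denoise → temporal → motion → analyze runs with JSON reports.

## Worked example

Train the denoiser on the reference phantom (16 volumes of 32×64×64 voxels,
~4 expected photons per voxel in bright structure) and measure the gain
against the known clean scene:

```python
import numpy as np
from tagspark import (PhantomSpec, make_dataset, NetworkConfig, TrainingConfig,
                      build_network, train, denoise)
from tagspark.analysis_metrics import pcc, psnr

ds = make_dataset(PhantomSpec())          # seeded reference phantom
model = build_network(NetworkConfig(levels=2, base_channels=16), seed=1)
train(model, ds.noisy, TrainingConfig(epochs=20, seed=1, patch=(16, 32, 32)))
den = denoise(model, ds.noisy)

s = ds.photon_scale                       # photon counts per unit intensity
raw, clean = ds.noisy.data / s, ds.clean.data
print(f"PSNR raw      {psnr(clean, raw):.2f} dB")
print(f"PSNR denoised {psnr(clean, den.data / s):.2f} dB")
print(f"PCC  raw      {np.median([pcc(clean[t], raw[t]) for t in range(16)]):.3f}")
print(f"PCC  denoised {np.median([pcc(clean[t], den.data[t] / s) for t in range(16)]):.3f}")
```

Output (about 2 minutes on one CPU core):

```
PSNR raw      19.48 dB
PSNR denoised 31.41 dB
PCC  raw      0.582
PCC  denoised 0.963
```

The ~12 dB PSNR gain means the mean squared error against the clean scene
dropped ~16-fold; the per-volume Pearson correlation with the clean scene
rose from 0.58 to 0.96 while each frame was denoised strictly from its own
data, so fast single-frame events keep their amplitude and peak frame.

The same workflow from the shell:

```bash
tagspark simulate --seed 7 --out sim/
tagspark denoise --in sim/noisy.tif --z-depth 32 --out denoised.tif --seed 1 --epochs 20
tagspark metrics --in denoised.tif --ref sim/clean.tif --z-depth 32
```

## Documentation

See `docs/methods.md` for the model, its assumptions, what the phantom does
and does not emulate, numerical choices and known limitations.
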