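# axsize

Streamline-specific axon diameter index from multi-shell, multi-diffusion-time
diffusion-weighted MRI.

## The problem

Axon diameters vary systematically between white-matter pathways and set
conduction velocity, so mapping them in vivo matters for connectomics and for
interpreting pathology.  DW-MRI methods that estimate an axon diameter index
(ADI) voxel by voxel assume a single fiber population per voxel; in the ~90%
of white-matter voxels where bundles cross, they overestimate badly, and
averaging a voxel-wise map along a tract (tractometry) inherits that bias.

`axsize` instead anchors the microstructure model to the tractogram.  The
signal of every white-matter voxel is written as a non-negative combination
of compartment signatures,

    y = A x + eta,        argmin_{x >= 0} || A x - y ||^2

where the columns of `A` are, per streamline, impermeable-cylinder signals
(Gaussian-phase-distribution closed form) at 12 fixed diameters from 1.5 to
7 um oriented along the streamline's local tangent and weighted by the
streamline-voxel intersection length; and, per voxel, zeppelin tensors (four
perpendicular diffusivities) and an isotropic ball.  The fitted cylinder
coefficients of a streamline are its volume-weighted cylinder diameter
distribution, and the streamline ADI (sADI) is the weighted mean over the
2.0–6.5 um bins (the end bins are catch bins for axons outside the sensitive
range).  Crossing bundles are disentangled because each streamline carries
its own contribution through every voxel it traverses.

The package includes everything needed to validate the estimator without
scanner data: a 45-degree crossing-bundle phantom (gamma-distributed
cylinder radii, tortuosity-coupled extra-axonal tensors, optional Watson
orientation dispersion, Rician noise), the voxel-wise single-population
baseline it is compared against, and scripted SNR / dictionary-density /
dispersion sweeps.

## Worked example

Build the crossing phantom, add Rician noise at SNR 50, and fit both
estimators:

```python
import numpy as np
from axsize import (BundleDiameterModel, VoxelwiseDiameterModel,
                    add_rician_noise, build_phantom)

phantom = build_phantom(grid=(40, 40, 1), n_streamlines=30, seed=1)
noisy = add_rician_noise(phantom.signal, snr=50, rng=1)

model = BundleDiameterModel.from_phantom(phantom)
res = model.fit(signal=noisy)
print(res.summary())

vox = VoxelwiseDiameterModel.from_phantom(phantom, signal=noisy).fit(
    voxels=phantom.region_voxels(1)[:100])
print(vox.summary())
```

```
Streamline axon diameter index (NNLS dictionary fit)
  voxels: 794  measurements/voxel: 365  columns: 5290
  solver: fista, 488 iter, converged: True
  relative residual ||Ax-y||/||y||: 0.0539
 bundle  n streamlines  bundle ADI [um]  median sADI [um]  undefined sADI
bundleA             30            2.878             2.868               0
bundleB             30            4.078             4.073               0
Voxel-wise axon diameter index (single fiber population)
  fitted voxels: 100  undefined ADI: 62
  ADI [um]: mean 3.212  median 3.204  range [2.000, 4.733]
```

The generating truth is a 2.70 um bundle (vertical, intra fraction 0.3)
crossing a 4.00 um bundle (diagonal, fraction 0.6) at 45 degrees.  The
streamline fit recovers 2.88/4.08 um — the small-bundle excess comes from
excluding the 1.5 um catch bin, i.e. from the acquisition's sensitivity
floor, not from crossing contamination.  The voxel-wise baseline on the
small bundle's own single-fiber voxels averages 3.21 um on this noise
realization, and over half its voxels return an undefined ADI (all
cylinder weight in the catch bins); in crossing voxels it climbs further.
The relative residual is the fitted model's misfit on the noisy volume.

A thin CLI wraps the same functionality:

```bash
axsize simulate --out phantom/ --snr 50 --seed 1
axsize fit --dwi phantom/signal.nii --mask phantom/mask.nii \
    --tractogram phantom/bundleA.tck --tractogram phantom/bundleB.tck \
    --scheme phantom/protocol.scheme --out fit
axsize experiment snr --out snr.csv --seed 1
```

## Documentation

See `docs/methods.md` for the model assumptions, the fixed diffusivities,
the phantom's construction, the solver's stopping rule (and why the
degenerate dictionary makes it part of the method), and known limitations.
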