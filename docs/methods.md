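# Methods

## Model

The package estimates a per-streamline axon diameter index from multi-shell,
multi-diffusion-time pulsed-gradient spin-echo (PGSE) DW-MRI.  All voxel
signals inside a white-matter mask are stacked into one vector `y` and
expressed as a non-negative linear combination `y = A x + eta` of three kinds
of atoms:

* **Cylinder columns** — for every streamline and every diameter `d_i` of a
  fixed grid, the signal of an impermeable parallel cylinder oriented along
  the streamline's local tangent, weighted in each traversed voxel by the
  intersection length normalized by voxel size.  The perpendicular
  attenuation uses the Gaussian phase distribution (GPD) closed form, a
  series over roots of the derivative of the order-1 Bessel function;
  parallel diffusion is free with fixed `d_par`.
* **Zeppelin columns** — per voxel and per principal diffusion direction,
  axially symmetric tensors with fixed `d_par` and one column for each of
  four perpendicular diffusivities, modelling the extra-axonal space.
* **Ball columns** — one isotropic tensor per voxel (CSF).

The coefficients are found by non-negative least squares,
`argmin_{x>=0} ||Ax - y||^2`.  The twelve cylinder coefficients of a
streamline are its volume-weighted cylinder diameter distribution; the
streamline axon diameter index (sADI) is the weighted mean over the
*included* bins, excluding the smallest (1.5 um) and largest (7 um)
diameters, which act as catch bins for axons outside the sensitive range of
the acquisition.  A bundle's distribution is the column-by-column sum over
its member streamlines and the bundle ADI is the weighted mean of that sum.

Fixed physical parameters (values conventional for in-vivo white matter):

| parameter | value | meaning |
|---|---|---|
| `d_par` | 1.7e-3 mm^2/s | longitudinal diffusivity (cylinders and zeppelins) |
| `d_iso` | 3.0e-3 mm^2/s | isotropic (CSF) diffusivity |
| `d_perp` | {0.5, 0.667, 0.833, 1.0}e-3 mm^2/s | zeppelin perpendicular set |
| diameter grid | 12 values, 1.5–7.0 um | cylinder diameters; ends excluded from the index |
| gamma | 2.6752e8 rad/s/T | proton gyromagnetic ratio |

The acquisition is the 300 mT/m Connectom protocol: two b-values (1000 and
4000 s/mm^2) at four diffusion times (Delta = 17.3, 30, 42, 55 ms, delta =
7 ms), 30/60 directions per weak/strong shell plus five b=0 images (365
measurements).  One published shell (b=4000, Delta=55 ms, G=175 mT/m) is
internally inconsistent — the timings imply b ~ 5656 s/mm^2 — and is carried
as given data; the b-value used everywhere is recomputed from (G, delta,
Delta).

## Numerical choices

* GPD series: 32 Bessel-derivative roots by default; a convergence check
  against 64 roots agrees to 1e-6 over the whole diameter grid and
  protocol.  Validated against a brute-force reflecting random walk (1e5
  walkers): agreement within 0.9% over the grid, worst at 7 um.
* Streamline-voxel intersection: exact polyline clipping against the
  axis-aligned grid (half-open voxels), sub-segments assigned by midpoints;
  collinear points are merged first, so straight trajectories clip in one
  pass.  Entry weight = intersection length / voxel size.
* Solver: monotone FISTA (projected gradient, Nesterov momentum with a
  function-value safeguard and gradient restart) on unit-norm columns.  The
  forward products of all iterates are maintained as linear combinations of
  two cached matrix-vector products per iteration.  Dense per-voxel
  problems (the voxel-wise baseline) use the exact active-set path instead:
  it is faster at that size and removes any trajectory dependence from the
  baseline.
* Stopping: relative objective change per iteration < 1e-5, with a
  projected-gradient check (1e-6 relative) every 25 iterations and a
  1000-iteration cap.

### Non-uniqueness and the stopping rule

The streamline NNLS problem is degenerate: cylinder and zeppelin atoms can
trade weight with little change in the fitted signal, in particular because
the phantom's extra-axonal perpendicular diffusivities (0.7 x and 0.1 x
`d_par`) lie outside the zeppelin set.  On noise-free data the relative
residual plateaus at ~1.2% after roughly 1000 iterations while the
small-bundle index keeps drifting as mass migrates into the excluded 1.5 um
catch bin (about 3.0 at 500 iterations, 2.5 at 2000, 2.25 at 4000).  The
reported index is therefore a property of the optimization protocol, not of
the objective alone.  The package adopts the objective-change stopping rule
conventional in dictionary-based microstructure solvers (relative change
< 1e-5, reached after ~500 iterations on the phantom problems) and exposes
the tolerance, the iteration cap and the monotone objective history so the
sensitivity can be examined.  The voxel-wise baseline has the same
degeneracy per voxel; its active-set solutions park all cylinder weight in
the catch bins in a large fraction of noisy single-fiber voxels (undefined
ADI), which is why region summaries use the mean/median of the defined
voxels only.

## Synthetic phantom

Two straight bundles cross at 45 degrees on a 2 mm isotropic grid: a
vertical bundle of small axons (gamma distribution over radii, shape
3.2734, scale 0.2556, volume-weighted mean diameter 2.70 um, intra-axonal
fraction 0.3) and a diagonal bundle of large axons (shape 3.5027, scale
0.3655, mean 4.00 um, fraction 0.6).  Extra-axonal zeppelins follow the
tortuosity approximation `d_perp = (1 - f_intra) d_par` (0.7 x, 0.4 x and
0.1 x `d_par` in the A-only, B-only and crossing regions); crossing voxels
carry 0.9 total intra-axonal fraction split 0.3/0.6 between the bundles,
with the remaining 0.1 split the same way between the two extra-axonal
tensors (the generating description states only the total).  Fractions sum
to one in every voxel, so the noise-free b=0 signal is exactly 1.

The intra-axonal mixture is represented by 200 stratified mid-quantile
draws of the volume-weighted radius law Gamma(shape+2, scale) with equal
weights.  Plain random draws of the same size leave +-0.2 um of sampling
error in the realized volume-weighted mean — larger than the effects under
study — whereas the stratified representation reproduces the closed form
`2 scale (shape+2)` to 0.1%.

Rician noise: `noisy = sqrt((S + e1)^2 + e2^2)` with `e1, e2 ~ N(0,
sigma^2)` and `sigma = S(b0)/SNR = 1/SNR`.

Optional Watson orientation dispersion (concentration kappa) is applied
per voxel to the cylinder orientations and, coherently, to the extra-axonal
tensor (averaged over the same samples); whether dispersion should also
deform the extra-axonal space is not specified by the generating
description, and coherent dispersion is the physically simpler choice.
For dispersion experiments the trajectories come from a Watson-stepping
surrogate tracker (0.5 mm steps along directions sampled about the bundle
axis with sign continuity) instead of a full probabilistic tractography
run; at kappa = inf the surrogate coincides with the ground-truth straight
trajectories, so it reproduces the dispersion-induced trajectory error but
not the intrinsic wander of iFOD2-style trackers on noise-free fields.

What the phantom does *not* emulate: realistic axon packing or undulation,
exchange/permeability, time-dependent extra-axonal diffusivity, T2/TE
effects, gray-matter partial volume, or curved trajectories.  Passing the
phantom study therefore shows correct recovery under the model's own
assumptions plus tortuosity-mismatched extra-axonal tensors and Rician
noise — not robustness to real tissue complexity.

## Validation experiments and problem sizes

The sweeps run at desk scale, chosen so each region still contains well
over the 100 voxels sampled for the baseline: a single-slice 40 x 40 grid
(250 / 394 / 150 voxels in the A-only / B-only / crossing regions), 30
ground-truth streamlines per bundle and 20 Rician noise realizations, with
100 voxels sampled per region for the voxel-wise method.  Each realization
feeds both estimators (paired design), and every sweep is a deterministic
function of its configuration and seed.  The phantom module itself defaults
to a 40 x 40 x 3 grid with 500 streamlines per bundle.

At SNR 50 the streamline estimator recovers bundle indices of ~2.86 um and
~4.07 um for generating truths of 2.70/4.00 um; the small-bundle
overestimate is dominated by the exclusion of the 1.5 um catch bin, which
removes the part of the gamma density below the acquisition's sensitivity
floor.  The voxel-wise baseline overestimates more (~3.3 um and ~4.7 um)
and degrades further in crossing voxels, reproducing the qualitative
ordering that motivates the streamline-anchored formulation.  The
large-bundle baseline value is sensitive to the absence of regularization
in the per-voxel fit: reference voxel-wise implementations add a ridge
penalty that damps the noise-driven selection of large-diameter atoms, and
reproducing their exact numbers would require reproducing that penalty,
which is out of scope here.

## Known limitations

* The index depends on the solver trajectory wherever the dictionary is
  degenerate (see above); comparisons across software must match stopping
  rules.
* The diameter grid's 1.5 um floor makes the method insensitive to the
  bulk of small axons; indices are interpretable only within the included
  2.0–6.5 um range.
* The surrogate tracker underestimates trajectory errors of real
  probabilistic tractography at high concentration (low dispersion).
* Histology comparison utilities (sectorization, count-to-volume
  conversion) are implemented and property-tested but not validated against
  a histological dataset here.
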