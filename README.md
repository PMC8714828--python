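# topoivim

Topological two-level fitting of the bi-exponential IVIM model for
diffusion MRI, with conventional baseline fitters, a Shepp-Logan
digital phantom with multi-coil noise, and an evaluation harness.

## The problem

Intravoxel incoherent motion (IVIM) imaging decomposes the
diffusion-weighted signal of each voxel into tissue-water diffusion and
capillary pseudo-diffusion (perfusion) compartments:

    S(b)/S0 = f·exp(−b·D*) + (1 − f)·exp(−b·D)

with perfusion fraction *f*, diffusivity *D* and pseudo-diffusivity
*D\** (mm²/s). The model is symmetric under swapping the compartments
and nearly flat in *D\** whenever *f* is small, so the least-squares
surface is bimodal with long degenerate valleys — conventional
voxelwise solvers (segmented two-stage fitting, local nonlinear least
squares, MCMC) produce notoriously unstable *D\** maps.

`topoivim` fits the model in two levels:

1. **Level 1 — variable projection.** The fraction is eliminated in
   closed form, leaving a *reduced* functional over the two rates only,
   which is better conditioned and cheap to minimize globally. A
   simplicial-homology optimizer (Sobol sampling → Delaunay complex →
   minimizer pool via star domains → bounded local refinement, with
   sample doubling until the pool is invariant) enumerates *every*
   minimum of the reduced surface.
2. **Level 2 — penalized refinement.** The best candidate seeds a
   global search of the full 3-D functional in a box around it, with a
   swap-invariant low-perfusion penalty `λ·D*²` (active for `f ≤ 0.2`,
   weight adapted to the voxel's noise level) that selects the physical
   end of the flat *D\** valleys.

See `docs/methods.md` for the model, optimizer, penalty calibration,
phantom and noise model in detail.

## Worked example

```python
import numpy as np
from topoivim import AcquisitionScheme, IVIMModel
from topoivim.phantom import ivim_bvalues, make_phantom, PhantomSpec

# a small noisy phantom: 32x32, one slice at SNR 50, 16 b-values
spec = PhantomSpec(shape=(32, 32, 1), bvalues=ivim_bvalues(16),
                   snr_per_slice=(50.0,), seed=7)
phantom = make_phantom(spec)

model = IVIMModel(phantom.dwi, phantom.scheme, mask=phantom.tissue_mask)
result = model.fit(method="topopro", seed=7)
print(result.summary())
```

prints

```
IVIM fit results
================
method:          topopro
voxels fitted:   512
b-values:        16 (max 1000 s/mm2)
flagged voxels:  0

parameter         mean      median         min         max
f              0.13795     0.10355   0.0023062         0.5
D            0.0014155  0.00082675  0.00025902   0.0048205
Dstar         0.011711   0.0079267       1e-05     0.12554
```

The median fitted parameters track the phantom's dominant tissue class
(normal tissue: f = 0.10, D = 0.0008, D\* = 0.010 mm²/s); the means sit
higher because the map also contains the high-perfusion tumor class
(f = 0.30, D\* = 0.030) and the fast-decaying cavity/CSF regions
(D = 0.003). No voxel raised a quality flag. `result.f`, `result.D`,
`result.Dstar` are the parameter maps; `result.to_dataframe()` gives a
per-voxel table and `result.save(outdir)` writes NIfTI maps with a JSON
sidecar.

The same pipeline is available from the shell:

```bash
topoivim --seed 7 simulate --nx 64 --ny 64 --slices 1 --snr 10 --out phantom/
topoivim --seed 7 fit --dwi phantom/dwi.nii.gz --bvals phantom/dwi.bval \
         --mask phantom/labels.nii.gz --method topopro --out maps/
topoivim evaluate --est-dir maps/ --gt-dir phantom/ --out metrics.csv
topoivim retest --dwi phantom/dwi.nii.gz --bvals phantom/dwi.bval --out retest.csv
```

`fit --method` also accepts `segmented`, `bayesian`, `nls` and `shgo`
(the global optimizer without the two-level machinery), so methods can
be compared on identical data.

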