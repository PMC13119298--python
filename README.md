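# polodf

Spatio-angular reconstruction for polarized fluorescence microscopy (PFM).

Fluorophores are dipoles: how much light they absorb and where they radiate it
depends on their 3D orientation. A polarized microscope that records a stack
of intensity volumes `i_p(r)` under different excitation polarizations `p`
therefore measures a *joint* projection of the sample's density and
orientation structure,

    i_p(r_d) = ∫∫ h_p(r_d − r_o, ŝ) f(r_o, ŝ) dr_o dŝ ,

where `f(r, ŝ)` is the six-dimensional spatio-angular distribution (an
orientation distribution function, ODF, at every voxel) and `h_p(r, ŝ)` the
dipole point-spread function. `polodf` simulates this forward model for
polarized wide-field, light-sheet (SPIM) and dual-view light-sheet (diSPIM)
geometries, and solves the inverse problem.

The core estimator is the **efficient generalized Richardson–Lucy (eGRL)**
iteration. The classical generalized RL treats the problem as
maximum-likelihood expectation-maximization over the dense (voxel ×
orientation) hyperspace, which is accurate but explodes in memory. eGRL keeps
the same multiplicative structure but

* represents every angular quantity by its 15 even-degree real
  spherical-harmonics coefficients `F_lm` (`l ∈ {0,2,4}` — all an imaging
  system with quadratic dipole response can transmit),
* precomputes the back-projected data `E_lm = Σ_p h_p(−r) * i_p` and the
  combined forward–backward operator `H^comb(ν)` (a 15×15 matrix per spatial
  frequency) outside the loop, and
* performs the per-voxel ratio and update steps as ODF division and
  multiplication directly in coefficient space through a precomputed Gaunt
  tensor.

Each iteration is then one frequency-domain 15×15 application, one per-voxel
15×15 solve and one per-voxel Gaunt product. Alongside eGRL the package ships
the dense GRL baseline, the decoupled eGRL-p ablation, a per-frequency
SVD/Tikhonov inverse, synthetic phantoms (shell, spheres, helices, DNA-like
double helix, GUV), ODF statistics (density, peak and principal orientation,
generalized fractional anisotropy, order parameter) and the similarity
metrics SSIM / OSIM / ONCC / PSIM, plus a blockwise crop–reconstruct–stitch
pipeline for large volumes.

## Worked example

```python
import numpy as np
from polodf import (OpticalConfig, preset_scheme, system_psf, make_shell,
                    forward_project, ReconstructionSettings, egrl_dualview,
                    SphereGrid)
from polodf.metrics import compare_fields

truth = make_shell((32, 32, 32), radius=11.0, sigma=1.0)   # radial dipoles
cfg = OpticalConfig()                    # NA 1.1/0.67 diSPIM, 130 nm voxels
scheme = preset_scheme("scheme18")       # 9 polarization/tilt states per view
resp = {v: system_psf(cfg, scheme.for_view(v), truth.shape,
                      modality="dispim", pad=8) for v in "AB"}
meas = {v: forward_project(truth, resp[v]) for v in "AB"}
rec = egrl_dualview(meas["A"], meas["B"], resp["A"], resp["B"],
                    ReconstructionSettings(iterations=10))
report = compare_fields(truth, rec, SphereGrid.fibonacci(1000))
print(f"SSIM {report.ssim:.3f}  ONCC {report.oncc:.3f}  PSIM {report.psim:.3f}")
```

prints (10 alternating dual-view cycles, noise-free):

```
SSIM 0.909  ONCC 0.904  PSIM 0.975
```

i.e. the recovered density correlates strongly with the ground truth, the
per-voxel ODF shapes match at 0.90 correlation, and the peak orientation axes
agree to `⟨|cos θ|⟩ = 0.975` (about 13° typical deviation) on the shell.

The same pipeline is available from the shell:

```sh
polodf phantom --kind double_helix --size 64 --out gt.h5
polodf simulate --gt gt.h5 --scheme scheme18 --out-dir stacks/
polodf reconstruct --algo egrl --scheme scheme18 --stacks stacks/ --out rec.h5
polodf metrics --gt gt.h5 --est rec.h5 --out report.json
```

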