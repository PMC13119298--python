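# Methods

This note documents the models implemented in `polodf`, the parameter choices
that matter, what the synthetic experiments do and do not establish, and the
numerical decisions taken where the design was genuinely open.

## The spatio-angular forward model

A voxel's fluorophore population is an orientation distribution function
(ODF) `f(r, ŝ)` on the unit sphere. The measured intensity under excitation
polarization `p̂` is the spatio-angular convolution of `f` with the dipole
PSF `h_p(r, ŝ)`. Because excitation probability (`∝ |p̂·ŝ|²`) and high-NA
vectorial detection are both quadratic in the dipole components, `h_p` is
exactly band-limited to even spherical-harmonics degrees `l ≤ 4`; we
represent all angular quantities by the corresponding 15 real orthonormal SH
coefficients (cosine harmonics for `m > 0`, sine for `m < 0`, no
Condon–Shortley phase; channel order `(0,0), (2,−2)…(2,2), (4,−4)…(4,4)`).

**Excitation.** `P_lm(p̂)` are the coefficients of `3|p̂·ŝ|²`:
`P_00 = 2√π`, `P_2m = (8π/5) Y_2m(p̂)`, all `l = 4` channels zero.

**Detection.** The two transverse field components produced in the pupil by
each dipole component are the aplanatic vectorial pupil functions
`g_ij(ρ, φ)` with `ρ = |τ|/v_m = sin θ` (radial pupil coordinate normalized
by the medium frequency `v_m = n0/λ`), apodized by `(1−ρ²)^{-1/4}` over the
aperture `|τ| < v_c/2 = NA/λ`, defocused by `exp[i2π r∥ √(v_m²−|τ|²)]` and
Fourier-transformed to the detector. The per-channel detection PSF is the
Gaunt contraction of the dipole-component irradiance matrix
`B_jj' = Σ_i β_ij β*_ij'` with the degree-1 harmonics; only `l ∈ {0, 2}`
survives. Detection PSFs are normalized so the orientation-averaged response
has unit energy.

**Geometries.** Arrays are `(z, y, x)`. View A detects along `z`; its light
sheet propagates along `x` with transverse polarization `p̂(α) = ŷcosα +
ẑsinα` and Gaussian thickness factor `exp[−2(r·n̂/w0)²]`. View B is the
`x↔z`-exchanged geometry, realized *exactly* on the voxel grid by an axis
transpose plus the real Wigner view-change blocks (see below). Wide-field
uses epi geometry: illumination along the detection axis, `p̂` in the focal
plane, no sheet. Sheet tilt steers the beam (and `p̂`, and the sheet normal)
about `ŷ`, the axis orthogonal to both optical axes — this is what carries
the polarization encoding out of the two transverse planes; a rotation about
the propagation axis would be degenerate with the transverse angle and was
therefore rejected.

**The view-change blocks.** On even degrees, the map that exchanges the two
optical axes (`x↔z`) coincides with a proper 180° rotation about
`(x̂+ẑ)/√2` because point inversion acts trivially there. Its `l = 2`
coefficient block is

    [[0, 1, 0, 0, 0], [1, 0, 0, 0, 0], [0, 0, -1/2, 0, √3/2],
     [0, 0, 0, 1, 0], [0, 0, √3/2, 0, 1/2]]

(rows/cols `(2,−2)…(2,2)`). The blocks are computed by exact quadrature, are
orthogonal and involutive, and pin down the package's SH sign convention. A
proper ±90° rotation about `ŷ` alone cannot reproduce this matrix (it sends
the `xz` harmonic to its negative); only the axis-exchange reading is
consistent, and it is the physically relevant one for a second objective.

## Reconstruction

**Dense GRL (baseline).** MLEM over (voxel × direction) samples with the
per-orientation sensitivity normalizer `s(ŝ) = Σ_p Σ_r h_p(r, ŝ)`. Its
Poisson log-likelihood is non-decreasing; memory grows with the direction
count, so it is guarded to grids ≤ 32³. Orientations in the acquisition null
space (e.g. dipoles along a single view's illumination axis) get a relative
`1e-12` sensitivity floor so their updates decay instead of dividing 0/0.

**eGRL.** The restructured iteration: back-project the data once
(`E_lm = Σ_p h_p(−r) * i_p`), precompute the combined operator
`H^comb_{lm,l'm'}(ν) = Σ_p conj(OTF_p,lm) OTF_p,l'm'`, then iterate
FBP (apply `H^comb`), DV (per-voxel ODF division through the Gaunt system
`M(den) x = num`), and Update (per-voxel Gaunt product). Reordering the
ratio (divide after back-projecting) makes the scalar limit the ISRA-ordered
variant of Richardson–Lucy rather than classic RL; both orderings share
their fixed points and agree closely in practice (density SSIM ≈ 0.998,
ONCC ≈ 0.98 against the dense MLEM on a 16³ shell). The SH path is validated
against a dense restructured oracle to ~1e-14. Convolutions are linear:
volumes are zero-padded (default 16 voxels) and cropped on output; the
padding margin behaves like unmeasured zeros, the usual RL edge condition.

The MLEM sensitivity normalizer cancels identically in the restructured
ratio (it enters numerator and denominator linearly), so eGRL carries none
and the back projector is the pure spatial reflection, i.e. `conj(OTF)`.

Initialization is a uniform angular distribution whose density channel is
the summed raw data (all polarizations; both views for dual-view).
Dual-view reconstruction alternates one half-step per view per cycle;
10 cycles is the default (20 for single view).

**DV conditioning.** The per-voxel 15×15 Gaunt system gets a relative ridge
`λ = dv_ridge · |trace(M)|/15` (default `dv_ridge = 1e-6`) that shrinks the
error map toward the *unit function* (no update) rather than toward zero:
since `M·unit = den`, exact fixed points remain exact at any ridge. Voxels
whose forward-back-projected density falls below `1e-8` of the maximum are
frozen (unit error map), as are voxels with non-finite solves. The same
regularization is used by the standalone `odf_divide`, with an absolute
fallback so an all-zero denominator still returns finite values.

**eGRL-p (ablation).** Scalar RL per polarization channel, then a per-voxel
angular iteration with spatially integrated responses. It exists to
demonstrate that decoupling density and orientation estimation degrades the
ODF recovery, and the tests assert exactly that direction of effect.

**SVD/Tikhonov.** Per spatial frequency the (measurements × 15) transfer
matrix is factorized and inverted with filter `μ/(μ²+η)`; dual-view data
concatenate along the measurement axis. `η` defaults to 0.1; for simulations
with ground truth it is searched over `10^-8 … 10^0` in `10^0.1` steps,
maximizing PSIM (on the 32³ noisy shell the search lands at ≈ 0.1).

## Phantoms

Per-voxel ODFs are Watson-type axial kernels `exp(κ(μ̂·ŝ)²)` projected to
`l ≤ 4`, with `κ` mapped from a requested generalized fractional anisotropy
(GFA) via a precomputed monotone lookup (band-limited GFA saturates at
≈ 0.966). Geometry defaults follow the printed phantom definitions: shell
64³/radius 30 voxels/1-voxel thickness/Gaussian σ = 2; spheres with central
densities 500–900 counts and radii 2–6 voxels; helices with 600 nm radius
and 1000 nm pitch, tangential dipoles, 20³-voxel bounding boxes; DNA-like
double helices with 554/478 nm strand spacing (chord at equal height) and
7020/7280 nm pitch, GFA ramping bottom→top; GUV membranes of 5/10 µm
diameter with surface-normal dipoles. Band-limited truncation gives the
kernels small negative side lobes (a few % of the peak at GFA 0.8); the
default mid-range anisotropies keep them minor.

## Acquisition schemes

The shipped presets (scheme18/8/6: 9/4/3 states per view) are *stand-ins*:
uniformly spaced transverse polarization angles combined with a ±20° sheet
tilt spread, since the published modulation tables are not reproduced here.
The tilt spread matters: without it the polarization vectors of each view
stay in one plane and orientation recovery degrades visibly (median shell
peak-orientation error 11.7° with flat scheme6 vs 7.1° with scheme18 at
32³). scheme18 is the package's canonical dual-view acquisition.

## Validation experiments and their scope

The simulation experiments keep all physical parameters (130 nm voxels,
NA 1.1/0.67, nm-scale phantom geometry, 488 nm emission) and shrink only the
grid (16³–64³) to keep runtimes at minutes on one CPU.

* **Density equivalence.** On the noise-free 64³ double-helix simulation
  with scheme18, the eGRL density map matches scalar RL deconvolution of the
  polarization-averaged stacks at windowed SSIM 0.9995 (20 iterations). The
  two estimators report density on different flux scales (object counts vs
  normalized-PSF intensity), so the RL map is mean-matched before the
  comparison; without that unit normalization the SSIM luminance term
  saturates the score at ≈ 0.97 regardless of structure.
* **Orientation bias.** With Poisson noise at 5 dB on a radial shell, the
  SVD baseline's peak orientations pile up along one axis (max axis-fraction
  deviation ≈ 0.33 from uniform) while eGRL stays near-uniform (≈ 0.02).
* **Motion sensitivity.** Rigid drift distributed in equal sub-steps across
  the modulation sequence degrades the peak-orientation map. On the helix
  phantom the loss grows roughly linearly with total drift — ≈ 4% at 65 nm,
  ≈ 12% at 130 nm, ≈ 46% at 1 µm (48³, scheme18, 10 cycles). This is a
  property of the phantom's orientation scale: the tangent field decorrelates
  over ~1–2 voxels, so a drift comparable to the 1 µm helix pitch scrambles
  the per-voxel modulation ratios that any orientation estimator relies on.
  Robustness of the few-percent kind at micrometer drift should only be
  expected for structures that are smooth at that scale (cells, vesicles).

What passing these experiments shows: the SH-domain algebra, the dipole PSF
model, the projector pair and the iterative estimators are mutually
consistent and recover planted spatio-angular structure under the simulated
conditions. What they do not show: performance on real data with registration
error, depth-dependent aberrations, background, or detector noise beyond the
Poisson model — none of which the simulator emulates.

## Numerical choices

* Quadrature: Gauss–Legendre × uniform-azimuth product grids, exact for all
  band-limited integrands (Gaunt entries to degree 12); antipodally
  symmetrized Fibonacci lattices (default 2562 points) for argmax searches
  and rendering.
* Peak orientations use a two-round local refinement around the grid argmax
  (resolution well below the lattice spacing ~4°); axes are canonicalized to
  the `z ≥ 0 → y ≥ 0 → x ≥ 0` hemisphere. Grid ties break toward the lowest
  direction index.
* The order parameter uses the `⟨P₂(ŝ·n̂)⟩` normalization, range
  `[−1/2, 1]`; it depends only on the `l = 2` channels.
* Large runs may use float32/complex64 (`ReconstructionSettings.dtype`);
  the per-voxel DV solves run through a fused numba kernel (Gaussian
  elimination with partial pivoting over the sparse Gaunt couplings) with a
  pure-numpy fallback.
* Blockwise processing trims a reconstruction halo (default: half the PSF
  support) before blending; trapezoidal ramp weights are normalized to an
  exact partition of unity, making stitching seam-free and order-independent.
* Non-negativity: no in-loop clamping; on output, density-channel negatives
  within `1e-6` of the peak are clipped to zero and larger violations are
  reported as warnings.

## Known limitations

* The acquisition presets are not the published modulation tables; absolute
  comparisons against instrument data require entering the real scheme.
* The PSF model is aberration-free and index-matched; no measured-PSF import
  beyond simple averaging.
* Sheet tilt changes only the illumination geometry, not the detection
  pupil; large tilts on a real instrument would also vignette.
* eGRL follows the restructured (ISRA-ordered) update; users wanting strict
  MLEM semantics at small scale should use the dense GRL path.
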