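"""Dipole point-spread functions for polarized wide-field, SPIM and diSPIM.

The camera irradiance produced by a single fluorescent dipole depends jointly
on its position, its orientation, and the excitation polarization.  Because the
dipole dependence of both excitation (|p.s|^2) and high-NA vectorial detection
is quadratic, each measurement's response lives entirely in the even
spherical-harmonics band l <= 4 and is represented as 15 per-channel volumes
H_{p,lm}(r).

Geometry convention: arrays are (z, y, x); view A detects along z with
illumination propagating along x; view B is the x<->z exchanged geometry
(detection along x, illumination along z), realized exactly on the voxel grid
by an axis transpose plus the real Wigner view-change blocks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sp_fft

from .gaunt import GauntTensor, gaunt_dipole_couplings, gaunt_tensor, odf_multiply
from .sphere import N_CHANNELS
from .wigner import wigner_y90

TWO_SQRT_PI = 2.0 * np.sqrt(np.pi)


# --------------------------------------------------------------------- config
@dataclass(frozen=True)
class OpticalConfig:
    """Optical parameters of one (or both) detection arms.

    diSPIM defaults: asymmetric NA pair 1.1 (view A) / 0.67 (view B), water
    immersion (n0 = 1.333), 488 nm emission preset, 130 nm isotropic voxels.
    ``sheet_waist`` is the 1/e^2 light-sheet half-thickness parameter w0 in nm.
    """

    na: float = 1.1
    na_b: float = 0.67
    wavelength: float = 488.0
    n0: float = 1.333
    voxel_size: float = 130.0
    sheet_waist: float = 1200.0

    def __post_init__(self) -> None:
        for na in (self.na, self.na_b):
            if not 0.0 < na < self.n0:
                raise ValueError(f"NA must satisfy 0 < NA < n0; got {na}")
        if self.sheet_waist <= 0:
            raise ValueError("sheet_waist must be positive")
        nyq = self.wavelength / (4.0 * self.na)
        if self.voxel_size > nyq:
            warnings.warn(
                f"voxel size {self.voxel_size} nm exceeds the Nyquist "
                f"threshold {nyq:.0f} nm for NA {self.na}",
                stacklevel=2,
            )

    @property
    def v_c(self) -> float:
        """Detection cutoff frequency 2 NA / lambda (view A), 1/nm."""
        return 2.0 * self.na / self.wavelength

    @property
    def v_m(self) -> float:
        """Medium frequency n0 / lambda, 1/nm."""
        return self.n0 / self.wavelength


@dataclass(frozen=True)
class PolarizationState:
    """One acquisition setting: view, transverse polarization angle, sheet tilt."""

    view: str = "A"
    pol_deg: float = 0.0
    tilt_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.view not in ("A", "B"):
            raise ValueError(f"view must be 'A' or 'B'; got {self.view!r}")

    @property
    def p_hat(self) -> np.ndarray:
        """Excitation polarization unit vector (x, y, z).

        View A illuminates along +x with p(0 deg) = y; view B is the x<->z
        swapped geometry (illumination along +z, p(0 deg) = y).  The sheet
        tilt steers the illumination beam about the y axis (the axis
        orthogonal to both optical axes), carrying the transverse polarization
        with it — this is what extends the polarization encoding out of the
        two transverse planes.
        """
        a = np.deg2rad(self.pol_deg)
        t = np.deg2rad(self.tilt_deg)
        base = np.array([0.0, np.cos(a), np.sin(a)])  # view A, transverse to x
        p = _axis_rotation(np.array([0.0, 1.0, 0.0]), t) @ base
        if self.view == "B":
            p = p[[2, 1, 0]]
        return p

    @property
    def p_hat_epi(self) -> np.ndarray:
        """Excitation polarization for epi-illumination (wide-field): the beam
        propagates along the detection axis, so p lies in the focal plane."""
        a = np.deg2rad(self.pol_deg)
        p = np.array([np.cos(a), np.sin(a), 0.0])  # view A: transverse to z
        if self.view == "B":
            p = p[[2, 1, 0]]
        return p

    @property
    def sheet_normal(self) -> np.ndarray:
        """Unit normal of the light sheet (detection axis tilted with the beam)."""
        t = np.deg2rad(self.tilt_deg)
        n = _axis_rotation(np.array([0.0, 1.0, 0.0]), t) @ np.array([0.0, 0.0, 1.0])
        if self.view == "B":
            n = n[[2, 1, 0]]
        return n


def _axis_rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + np.sin(angle) * K + (1.0 - np.cos(angle)) * (K @ K)


# --------------------------------------------------------------- acquisition
@dataclass(frozen=True)
class AcquisitionScheme:
    """Ordered modulation table: one PolarizationState per measurement."""

    entries: tuple[PolarizationState, ...]

    def __post_init__(self) -> None:
        if len(self.entries) == 0:
            raise ValueError("scheme must contain at least one entry")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def views(self) -> tuple[str, ...]:
        return tuple(sorted({e.view for e in self.entries}))

    def for_view(self, view: str) -> "AcquisitionScheme":
        sub = tuple(e for e in self.entries if e.view == view)
        return AcquisitionScheme(sub)


_PRESET_TABLES = {
    # per-view (pol_deg, tilt_deg) pairs: uniformly spaced transverse
    # polarizations combined with +/-20 deg sheet tilts so the polarization
    # encoding leaves the two transverse planes, as on the real instrument
    "scheme18": [(p, t) for t in (-20.0, 0.0, 20.0) for p in (0.0, 60.0, 120.0)],
    "scheme8": [(0.0, -20.0), (45.0, 20.0), (90.0, -20.0), (135.0, 20.0)],
    "scheme6": [(0.0, -20.0), (60.0, 0.0), (120.0, 20.0)],
}


def preset_scheme(name: str) -> AcquisitionScheme:
    """Dual-view presets (scheme18: 9 per view, scheme8: 4, scheme6: 3).

    The published acquisition tables are not reproduced here; these are
    stand-ins with the same measurement counts, combining uniformly spaced
    transverse polarization angles with a +/-20 degree sheet-tilt spread.
    """
    if name not in _PRESET_TABLES:
        raise ValueError(f"unknown scheme preset {name!r}")
    entries = []
    for view in ("A", "B"):
        for pol, tilt in _PRESET_TABLES[name]:
            entries.append(PolarizationState(view, pol, tilt))
    return AcquisitionScheme(tuple(entries))


# ------------------------------------------------------------- pupil / fields
def pupil_g(rho: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Pupil field components g_ij of a dipole, shape (2, 3) + rho.shape.

    ``rho`` is the radial pupil coordinate in units of v_m (= sin of the
    aperture angle, < NA/n0); i indexes the two transverse field components,
    j the dipole component (x, y, z).
    """
    ct = np.sqrt(np.clip(1.0 - rho**2, 0.0, None))
    g = np.empty((2, 3) + np.shape(rho))
    g[0, 0] = np.sin(phi) ** 2 + np.cos(phi) ** 2 * ct
    g[1, 0] = 0.5 * np.sin(2 * phi) * (ct - 1.0)
    g[0, 1] = 0.5 * np.sin(2 * phi) * (ct - 1.0)
    g[1, 1] = np.cos(phi) ** 2 + np.sin(phi) ** 2 * ct
    g[0, 2] = rho * np.cos(phi)
    g[1, 2] = rho * np.sin(phi)
    return g


class PupilResolutionError(ValueError):
    """Raised when the pupil grid undersamples the aperture."""


def pupil_fields(
    config: OpticalConfig,
    defocus: float,
    plane_shape: tuple[int, int],
    na: float | None = None,
    oversample: int = 1,
) -> np.ndarray:
    """Electric-field components beta_ij on the detector plane at one defocus.

    Returns complex array (2, 3, ny, nx): the 2D Fourier transform of
    A(tau) Phi(tau, defocus) g_ij(tau) over the aperture disk |tau| < v_c/2.
    ``defocus`` in nm; the output plane is sampled at the config voxel size.
    """
    na = config.na if na is None else na
    v_c = 2.0 * na / config.wavelength
    v_m = config.v_m
    ny, nx = plane_shape
    my = sp_fft.next_fast_len(max(ny, 64) * oversample)
    mx = sp_fft.next_fast_len(max(nx, 64) * oversample)
    fy = np.fft.fftfreq(my, d=config.voxel_size)[:, None]
    fx = np.fft.fftfreq(mx, d=config.voxel_size)[None, :]
    if min(my, mx) / config.voxel_size / 2.0 / v_c < 4.0:  # pragma: no cover
        raise PupilResolutionError("pupil grid coarser than the v_c sampling")
    tau = np.sqrt(fy**2 + fx**2)
    inside = tau < v_c / 2.0
    if inside.sum() < 9:
        raise PupilResolutionError("pupil grid coarser than the v_c sampling")
    phi = np.arctan2(fx, fy * np.ones_like(fx))
    rho = np.clip(tau / v_m, 0.0, 1.0 - 1e-12)
    apod = (1.0 - rho**2) ** (-0.25) * inside
    defoc = np.exp(2j * np.pi * defocus * v_m * np.sqrt(np.clip(1.0 - rho**2, 0.0, None)))
    pupil = apod * defoc
    g = pupil_g(rho, phi)
    beta = sp_fft.ifft2(pupil * g, axes=(-2, -1), norm="forward")
    beta = np.fft.fftshift(beta, axes=(-2, -1))
    cy, cx = my // 2, mx // 2
    return beta[..., cy - ny // 2 : cy - ny // 2 + ny, cx - nx // 2 : cx - nx // 2 + nx]


# ------------------------------------------------------------- detection PSF
def detection_psf(
    config: OpticalConfig,
    shape: tuple[int, int, int],
    na: float | None = None,
) -> np.ndarray:
    """Per-channel detection dipole PSF H^(det)_lm(r) for a z-axis arm.

    Returns (15, nz, ny, nx), centered at shape//2; only l in {0, 2} channels
    are nonzero (the dipole dependence of detected irradiance is quadratic).
    Normalized so the orientation-averaged PSF has unit total energy
    (sum_r H_00 = 2 sqrt(pi)).
    """
    nz, ny, nx = shape
    C = gaunt_dipole_couplings()  # (15, 3, 3)
    out = np.zeros((N_CHANNELS, nz, ny, nx))
    zs = (np.arange(nz) - nz // 2) * config.voxel_size
    for iz, z in enumerate(zs):
        beta = pupil_fields(config, z, (ny, nx), na=na)  # (2, 3, ny, nx)
        B = np.einsum("ij...,ik...->jk...", beta, beta.conj()).real
        out[:, iz] = (4.0 * np.pi / 3.0) * np.einsum("cjk,jk...->c...", C, B)
    total = out[0].sum()
    if total > 0:
        out *= TWO_SQRT_PI / total
    return out


# ----------------------------------------------------------------- excitation
def excitation_coeffs(p_hat: np.ndarray) -> np.ndarray:
    """SH coefficients P_lm of the excitation pattern 3 |p.s|^2.

    P_00 = 2 sqrt(pi) for any p; P_2m = (8 pi / 5) Y_2m(p); all l = 4
    channels vanish.
    """
    from .sphere import EVEN_CHANNELS, real_sph_harm

    p = np.asarray(p_hat, dtype=float)
    if abs(np.linalg.norm(p) - 1.0) > 1e-8:
        raise ValueError("excitation polarization must be a unit vector")
    out = np.zeros(N_CHANNELS)
    for i, (l, m) in enumerate(EVEN_CHANNELS):
        if l == 0:
            out[i] = 4.0 * np.pi * real_sph_harm(0, 0, p)
        elif l == 2:
            out[i] = 4.0 * np.pi * (2.0 / 5.0) * real_sph_harm(2, m, p)
    return out


# ------------------------------------------------------------ system response
@dataclass
class SystemResponse:
    """Per-measurement dipole PSFs in SH channels, plus Fourier forms.

    ``psf`` is (P, 15, wz, wy, wx) on the padded working grid (object shape
    plus ``pad`` on each side, to make FFT convolutions linear); ``otf`` its
    rfftn with the PSF center moved to the origin.  The back projector is the
    exact spatial reflection of the forward PSF, i.e. conj(otf) in Fourier
    space.  ``sens`` holds the per-channel spatially-and-measurement-summed
    response used by the dense MLEM normalizer.
    """

    psf: np.ndarray = field(repr=False)
    otf: np.ndarray = field(repr=False)
    entries: tuple[PolarizationState, ...]
    shape: tuple[int, int, int]
    pad: int
    voxel_size: float

    @property
    def n_measurements(self) -> int:
        return self.psf.shape[0]

    @property
    def work_shape(self) -> tuple[int, int, int]:
        return tuple(s + 2 * self.pad for s in self.shape)

    @property
    def sens(self) -> np.ndarray:
        s = self.psf.sum(axis=(0, 2, 3, 4))
        return np.maximum(s, 0.0) + 1e-12 * (s == 0)

    @property
    def back_otf(self) -> np.ndarray:
        return np.conj(self.otf)

    def for_view(self, view: str) -> "SystemResponse":
        idx = [i for i, e in enumerate(self.entries) if e.view == view]
        if not idx:
            raise ValueError(f"no measurements for view {view!r}")
        return SystemResponse(
            self.psf[idx],
            self.otf[idx],
            tuple(self.entries[i] for i in idx),
            self.shape,
            self.pad,
            self.voxel_size,
        )


def psf_to_otf(psf: np.ndarray) -> np.ndarray:
    """rfftn of a center-origin PSF stack over its last three axes."""
    shifted = np.fft.ifftshift(psf, axes=(-3, -2, -1))
    return sp_fft.rfftn(shifted, axes=(-3, -2, -1))


def make_back_projector(resp: SystemResponse) -> np.ndarray:
    """Spatial back-projector volumes h(-r), channel-wise (matched-reflected)."""
    back = sp_fft.irfftn(resp.back_otf, s=resp.work_shape, axes=(-3, -2, -1))
    return np.fft.fftshift(back, axes=(-3, -2, -1))


def _sheet_factor(
    work_shape: tuple[int, int, int], voxel_size: float, waist: float, normal: np.ndarray
) -> np.ndarray:
    wz, wy, wx = work_shape
    z = (np.arange(wz) - wz // 2)[:, None, None] * voxel_size
    y = (np.arange(wy) - wy // 2)[None, :, None] * voxel_size
    x = (np.arange(wx) - wx // 2)[None, None, :] * voxel_size
    proj = z * normal[2] + y * normal[1] + x * normal[0]
    return np.exp(-2.0 * (proj / waist) ** 2)


def system_psf(
    config: OpticalConfig,
    scheme: AcquisitionScheme,
    shape: tuple[int, int, int],
    modality: str = "dispim",
    pad: int = 16,
    G: GauntTensor | None = None,
    dtype=np.float64,
) -> SystemResponse:
    """Assemble the per-measurement system response for one modality.

    widefield: view-A detection, uniformly polarized illumination, no sheet.
    spim: view-A detection with the Gaussian light-sheet factor.
    dispim: dual-view; view-B detection channels are the view-A channels
    spatially transposed (x<->z) and mixed by the real Wigner view-change
    blocks, with the sheet along the view-B axis.
    """
    if modality not in ("widefield", "spim", "dispim"):
        raise ValueError(f"unknown modality {modality!r}")
    if modality != "dispim" and any(e.view == "B" for e in scheme.entries):
        raise ValueError(f"{modality} accepts view-A entries only")
    G = G or gaunt_tensor()
    work = tuple(s + 2 * pad for s in shape)
    det: dict[str, np.ndarray] = {}
    det["A"] = detection_psf(config, work)
    if any(e.view == "B" for e in scheme.entries):
        # view B: compute the z-axis detection PSF of the B arm on the
        # transposed grid, then map it into the common frame by the exact
        # x<->z transpose plus Wigner channel mixing
        det_b = detection_psf(config, (work[2], work[1], work[0]), na=config.na_b)
        rot = wigner_y90()
        det["B"] = rot.apply(np.swapaxes(det_b, 1, 3))
    psfs = np.empty((len(scheme), N_CHANNELS) + work, dtype=dtype)
    for i, entry in enumerate(scheme.entries):
        p_hat = entry.p_hat_epi if modality == "widefield" else entry.p_hat
        P = excitation_coeffs(p_hat)
        h = odf_multiply(P, det[entry.view], G)
        if modality in ("spim", "dispim"):
            h = h * _sheet_factor(
                work, config.voxel_size, config.sheet_waist, entry.sheet_normal
            )
        psfs[i] = h
    otf = psf_to_otf(psfs).astype(np.result_type(dtype, np.complex64))
    return SystemResponse(
        psf=psfs,
        otf=otf,
        entries=scheme.entries,
        shape=tuple(shape),
        pad=pad,
        voxel_size=config.voxel_size,
    )
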