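"""Forward simulation of polarized imaging, noise, and intensity calibration.

The measured intensity under modulation p is the spatio-angular projection
i_p(r) = sum_lm (H_{p,lm} * F_lm)(r): each SH channel of the object is blurred
by the matching channel of the dipole PSF and the channels are summed.
Convolutions are linear (zero-padded by the response's pad margin) and
executed in the Fourier domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sp_fft

from .field import SHField
from .psf import PolarizationState, SystemResponse


@dataclass
class MeasurementSet:
    """Ordered polarized intensity volumes with per-volume acquisition metadata."""

    volumes: np.ndarray = field(repr=False)  # (P, nz, ny, nx), photon counts
    meta: tuple[PolarizationState, ...] = ()
    voxel_size: float = 130.0

    def __post_init__(self) -> None:
        v = np.asarray(self.volumes)
        if v.ndim != 4:
            raise ValueError("volumes must be (P, nz, ny, nx)")
        if len(self.meta) != v.shape[0]:
            raise ValueError("meta length must equal the number of volumes")
        self.volumes = v

    def __len__(self) -> int:
        return self.volumes.shape[0]

    def for_view(self, view: str) -> "MeasurementSet":
        idx = [i for i, e in enumerate(self.meta) if e.view == view]
        if not idx:
            raise ValueError(f"no measurements for view {view!r}")
        return MeasurementSet(
            self.volumes[idx], tuple(self.meta[i] for i in idx), self.voxel_size
        )


def _pad(vol: np.ndarray, pad: int) -> np.ndarray:
    if pad == 0:
        return vol
    width = [(0, 0)] * (vol.ndim - 3) + [(pad, pad)] * 3
    return np.pad(vol, width)


def _crop(vol: np.ndarray, pad: int) -> np.ndarray:
    if pad == 0:
        return vol
    sl = (Ellipsis,) + (slice(pad, -pad),) * 3
    return vol[sl]


def forward_project(obj: SHField, resp: SystemResponse) -> MeasurementSet:
    """Simulate noise-free measurements of an SH field. Linear in the object."""
    if obj.shape != resp.shape:
        raise ValueError(f"object shape {obj.shape} != response shape {resp.shape}")
    work = resp.work_shape
    F = sp_fft.rfftn(_pad(obj.coeffs, resp.pad), axes=(-3, -2, -1))
    vols = np.empty((resp.n_measurements,) + obj.shape)
    for p in range(resp.n_measurements):
        spec = np.einsum("c...,c...->...", resp.otf[p], F)
        vol = sp_fft.irfftn(spec, s=work, axes=(-3, -2, -1))
        vols[p] = _crop(vol, resp.pad)
    # FFT round-off (and mild ODF truncation ringing) leaves small negatives;
    # anything larger is a model violation
    peak = np.abs(vols).max() or 1.0
    if vols.min() < -1e-3 * peak:
        import warnings

        warnings.warn("forward projection produced non-trivial negatives", stacklevel=2)
    np.maximum(vols, 0.0, out=vols)
    return MeasurementSet(vols, resp.entries, resp.voxel_size)


def back_project(meas: MeasurementSet, resp: SystemResponse) -> np.ndarray:
    """Adjoint of forward_project: sum_p H_p(-r) * i_p, on the working grid.

    Returns (15, wz, wy, wx); crop with pad to return to object coordinates.
    """
    work = resp.work_shape
    out = np.zeros((resp.psf.shape[1],) + work)
    for p in range(resp.n_measurements):
        spec = sp_fft.rfftn(_pad(meas.volumes[p], resp.pad), axes=(-3, -2, -1))
        out += sp_fft.irfftn(
            resp.back_otf[p] * spec, s=work, axes=(-3, -2, -1)
        )
    return out


def forward_project_moving(
    obj: SHField, resp: SystemResponse, shifts_nm: np.ndarray
) -> MeasurementSet:
    """Forward projection of a rigidly drifting object.

    ``shifts_nm`` is (P, 3) in (z, y, x) order: the object's displacement at
    the time each modulation is acquired.  Sub-voxel shifts are applied as
    Fourier phase ramps (band-limited interpolation).
    """
    shifts_nm = np.asarray(shifts_nm, dtype=float)
    if shifts_nm.shape != (resp.n_measurements, 3):
        raise ValueError("one (z, y, x) shift per measurement required")
    work = resp.work_shape
    F = sp_fft.rfftn(_pad(obj.coeffs, resp.pad), axes=(-3, -2, -1))
    freqs = [
        np.fft.fftfreq(work[0])[:, None, None],
        np.fft.fftfreq(work[1])[None, :, None],
        np.fft.rfftfreq(work[2])[None, None, :],
    ]
    vols = np.empty((resp.n_measurements,) + obj.shape)
    for p in range(resp.n_measurements):
        dz, dy, dx = shifts_nm[p] / resp.voxel_size
        ramp = np.exp(-2j * np.pi * (freqs[0] * dz + freqs[1] * dy + freqs[2] * dx))
        spec = np.einsum("c...,c...->...", resp.otf[p], F * ramp)
        vols[p] = _crop(sp_fft.irfftn(spec, s=work, axes=(-3, -2, -1)), resp.pad)
    np.maximum(vols, 0.0, out=vols)
    return MeasurementSet(vols, resp.entries, resp.voxel_size)


# ------------------------------------------------------------------- noise
def add_poisson_noise(
    meas: MeasurementSet, scale: float, seed: int
) -> tuple[MeasurementSet, float]:
    """Poisson photon noise at a given photon scale; returns (noisy, SNR dB).

    Counts are drawn as Poisson(scale * i); the SNR is computed from the
    *realized* noise, 10 log10(Mean(S^2) / Mean(N^2)) with S = scale * i and
    N = counts - S.  Deterministic per seed.
    """
    if scale <= 0:
        raise ValueError("photon scale must be positive")
    if np.any(meas.volumes < 0):
        raise ValueError("input intensities must be nonnegative")
    rng = np.random.default_rng(seed)
    S = scale * meas.volumes
    counts = rng.poisson(S).astype(float)
    noise = counts - S
    snr_db = 10.0 * np.log10(np.mean(S**2) / np.mean(noise**2))
    return MeasurementSet(counts, meas.meta, meas.voxel_size), float(snr_db)


def scale_for_snr(
    meas: MeasurementSet, target_snr_db: float, seed: int = 0
) -> float:
    """Photon scale at which Poisson noise yields the target SNR (expected-power).

    For Poisson noise E[N^2] = scale * i, so SNR(scale) is solved from
    Mean(S^2)/Mean(S) = 10^(SNR/10), giving a closed form; the realized SNR of
    :func:`add_poisson_noise` then fluctuates around the target.
    """
    i = meas.volumes
    m2, m1 = np.mean(i**2), np.mean(i)
    return 10.0 ** (target_snr_db / 10.0) * m1 / m2


# --------------------------------------------------------------- calibration
def calibration_correct(
    raw: MeasurementSet,
    cal: np.ndarray,
    lake: np.ndarray,
    ref: int = 0,
) -> MeasurementSet:
    """Correct per-modulation intensity drift against a uniform-slide calibration.

    g_p = g_p^(raw) * (cal_ref / cal_p) * (lake_p / lake_ref): the measured
    uniform-slide response removes the instrumental modulation while the
    simulated isotropic-lake response restores the ideal one.
    """
    cal = np.asarray(cal, dtype=float)
    lake = np.asarray(lake, dtype=float)
    if cal.shape != (len(raw),) or lake.shape != (len(raw),):
        raise ValueError("cal and lake must hold one scalar per measurement")
    if np.any(cal <= 0) or np.any(lake <= 0):
        raise ZeroDivisionError("cal and lake factors must be strictly positive")
    factors = (cal[ref] / cal) * (lake / lake[ref])
    return MeasurementSet(
        raw.volumes * factors[:, None, None, None], raw.meta, raw.voxel_size
    )


def mimic_polarized_beads(
    bead: dict[str, np.ndarray],
    lake: np.ndarray,
    meta: tuple[PolarizationState, ...],
    ref: int = 0,
    voxel_size: float = 130.0,
) -> MeasurementSet:
    """Synthesize polarized measurements from unpolarized bead volumes.

    Randomly oriented bead fluorophores respond to a polarization change only
    through a global intensity factor, taken from the isotropic-lake response:
    bead_{p,v}(r) = bead_v(r) * lake_{p,v} / lake_ref.
    """
    lake = np.asarray(lake, dtype=float)
    if np.any(lake <= 0):
        raise ZeroDivisionError("lake factors must be strictly positive")
    if lake.shape != (len(meta),):
        raise ValueError("lake must hold one scalar per scheme entry")
    vols = []
    for i, entry in enumerate(meta):
        if entry.view not in bead:
            raise ValueError(f"missing bead volume for view {entry.view!r}")
        vols.append(bead[entry.view] * (lake[i] / lake[ref]))
    return MeasurementSet(np.stack(vols), tuple(meta), voxel_size)
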