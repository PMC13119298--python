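"""Spatio-angular reconstruction: GRL, eGRL, eGRL-p and the SVD baseline.

Four estimators of the spatio-angular distribution from polarized stacks:

* ``grl_reconstruct`` — the dense generalized Richardson-Lucy baseline, an
  MLEM iteration carried out directly on (position x orientation) samples.
  Exact but memory-hungry; guarded to small grids.  Its ``restructured``
  variant reorders the ratio (back-project first, then divide in object
  space), which is the dense-domain mirror of eGRL and serves as its oracle.
* ``egrl_reconstruct`` / ``egrl_dualview`` — the efficient GRL: the same
  restructured iteration anchored entirely in the 15-channel spherical-
  harmonics domain.  The data back-projection and the combined
  forward-backward operator are precomputed outside the loop; each iteration
  is one frequency-domain 15x15 application (FBP), one per-voxel Gaunt-matrix
  solve (DV), and one per-voxel Gaunt product (Update).
* ``egrlp_reconstruct`` — the decoupled ablation: scalar RL per polarization
  channel, then an independent per-voxel angular estimation with
  spatially integrated responses.
* ``svd_reconstruct`` — per-frequency Tikhonov pseudoinverse of the SH-domain
  transfer matrix, with the PSIM-guided eta search.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sp_fft

from .field import SHField
from .gaunt import GauntTensor, gaunt_tensor
from .psf import SystemResponse
from .simulate import MeasurementSet, _crop, _pad
from .sphere import N_CHANNELS, SphereGrid, basis_matrix, unit_odf_coeffs

logger = logging.getLogger(__name__)

_EPS = 1e-30

try:  # numba accelerates the per-voxel 15x15 DV solves substantially
    import numba as _numba

    @_numba.njit(fastmath=True)
    def _batched_solve_impl(M, b):  # pragma: no cover - compiled
        n, k, _ = M.shape
        x = np.empty((n, k), dtype=M.dtype)
        for v in range(n):
            A = M[v].copy()
            y = b[v].copy()
            for c in range(k):  # gaussian elimination, partial pivoting
                piv = c
                amax = abs(A[c, c])
                for r in range(c + 1, k):
                    a = abs(A[r, c])
                    if a > amax:
                        amax = a
                        piv = r
                if piv != c:
                    for t in range(c, k):
                        tmp = A[c, t]
                        A[c, t] = A[piv, t]
                        A[piv, t] = tmp
                    tmp = y[c]
                    y[c] = y[piv]
                    y[piv] = tmp
                d = A[c, c]
                if d == 0.0:
                    d = 1e-30
                inv = 1.0 / d
                for r in range(c + 1, k):
                    f = A[r, c] * inv
                    if f != 0.0:
                        for t in range(c + 1, k):
                            A[r, t] -= f * A[c, t]
                        y[r] -= f * y[c]
            for c in range(k - 1, -1, -1):
                s = y[c]
                for t in range(c + 1, k):
                    s -= A[c, t] * x[v, t]
                x[v, c] = s / (A[c, c] if A[c, c] != 0.0 else 1e-30)
        return x

    def _batched_solve(M: np.ndarray, b: np.ndarray) -> np.ndarray:
        return _batched_solve_impl(np.ascontiguousarray(M), np.ascontiguousarray(b))

    @_numba.njit(fastmath=True)
    def _dv_update_kernel(  # pragma: no cover - compiled
        Ev, numv, denv, gi, gj, gk, gv, ridge, thresh, unit, out
    ):
        """Fused per-voxel DV + Update: build the sparse-Gaunt system M(den),
        ridge it toward the unit error map, solve, and Gaunt-multiply with the
        estimate — entirely in-cache per voxel."""
        n = Ev.shape[0]
        k15 = Ev.shape[1]
        nnz = gv.shape[0]
        for v in range(n):
            M = np.zeros((k15, k15), dtype=Ev.dtype)
            for t in range(nnz):
                M[gj[t], gk[t]] += gv[t] * denv[v, gi[t]]
            y = numv[v].copy()
            if ridge > 0.0:
                tr = 0.0
                for c in range(k15):
                    tr += M[c, c]
                lam = ridge * abs(tr) / k15
                for c in range(k15):
                    M[c, c] += lam
                    y[c] += lam * unit[c]
            if denv[v, 0] <= thresh:
                for c in range(k15):
                    out[v, c] = Ev[v, c]
                continue
            # gaussian elimination with partial pivoting
            ok = True
            for c in range(k15):
                piv = c
                amax = abs(M[c, c])
                for r in range(c + 1, k15):
                    a = abs(M[r, c])
                    if a > amax:
                        amax = a
                        piv = r
                if amax == 0.0:
                    ok = False
                    break
                if piv != c:
                    for t in range(c, k15):
                        tmp = M[c, t]
                        M[c, t] = M[piv, t]
                        M[piv, t] = tmp
                    tmp = y[c]
                    y[c] = y[piv]
                    y[piv] = tmp
                inv = 1.0 / M[c, c]
                for r in range(c + 1, k15):
                    f = M[r, c] * inv
                    if f != 0.0:
                        for t in range(c + 1, k15):
                            M[r, t] -= f * M[c, t]
                        y[r] -= f * y[c]
            err = np.empty(k15, dtype=Ev.dtype)
            if ok:
                for c in range(k15 - 1, -1, -1):
                    s = y[c]
                    for t in range(c + 1, k15):
                        s -= M[c, t] * err[t]
                    err[c] = s / M[c, c]
                for c in range(k15):
                    if not np.isfinite(err[c]):
                        ok = False
                        break
            if not ok:
                for c in range(k15):
                    out[v, c] = Ev[v, c]
                continue
            for c in range(k15):
                out[v, c] = 0.0
            for t in range(nnz):
                out[v, gk[t]] += gv[t] * Ev[v, gi[t]] * err[gj[t]]

except ImportError:  # pragma: no cover
    _dv_update_kernel = None

    def _batched_solve(M: np.ndarray, b: np.ndarray) -> np.ndarray:
        return np.linalg.solve(M, b[..., None])[..., 0]


_GAUNT_SPARSE_CACHE: dict[int, tuple] = {}


def _gaunt_sparse(G: GauntTensor) -> tuple:
    key = id(G.values)
    if key not in _GAUNT_SPARSE_CACHE:
        gi, gj, gk = np.nonzero(G.values)
        _GAUNT_SPARSE_CACHE[key] = (
            gi.astype(np.int64),
            gj.astype(np.int64),
            gk.astype(np.int64),
            G.values[gi, gj, gk].copy(),
        )
    return _GAUNT_SPARSE_CACHE[key]


@dataclass
class ReconstructionSettings:
    """Iteration counts and conditioning knobs shared by the estimators.

    ``iterations`` defaults to 20 for single-view and 10 for dual-view runs
    when left as None.  ``dv_ridge`` is the relative diagonal ridge of the DV
    (ODF division) solve; ``freeze_rel`` freezes voxels whose forward-
    back-projected density falls below this fraction of the maximum (their
    error map is the unit function, i.e. no update).  ``eta`` is the Tikhonov
    regularizer of the SVD baseline and ``eta_grid`` its search grid
    (10^-8 ... 10^0, factor 10^0.1).
    """

    iterations: int | None = None
    dv_ridge: float = 1e-6
    freeze_rel: float = 1e-8
    eta: float = 0.1
    eta_grid: np.ndarray = field(
        default_factory=lambda: 10.0 ** np.arange(-8.0, 0.0001, 0.1)
    )
    seed: int = 0
    dtype: np.dtype = np.float64

    def n_iter(self, dual_view: bool) -> int:
        if self.iterations is not None:
            if self.iterations < 1:
                raise ValueError("iterations must be >= 1")
            return self.iterations
        return 10 if dual_view else 20

    @property
    def cdtype(self) -> np.dtype:
        return np.result_type(self.dtype, np.complex64)


# =====================================================================
# eGRL
# =====================================================================
@dataclass
class EGRLOperators:
    """Precomputed pieces of the eGRL loop (one view).

    ``data_term`` is the back-projected data E_lm(r) = sum_p hback_p * i_p on
    the working grid; ``h_comb`` the combined forward-backward operator
    sum_p OTF_p,lm conj(OTF_p,l'm') — a Hermitian PSD 15x15 matrix per spatial
    frequency, independent of the polarization index thereafter.
    """

    data_term: np.ndarray = field(repr=False)  # (15, wz, wy, wx)
    h_comb: np.ndarray = field(repr=False)  # (15, 15, wz, wy, fx)
    work_shape: tuple[int, int, int]
    pad: int
    voxel_size: float


def egrl_precompute(
    meas: MeasurementSet, resp: SystemResponse, settings: ReconstructionSettings | None = None
) -> EGRLOperators:
    settings = settings or ReconstructionSettings()
    if meas.volumes.shape[1:] != resp.shape:
        raise ValueError("measurement and response grids differ")
    work = resp.work_shape
    cdt = settings.cdtype
    data_term = np.zeros((N_CHANNELS,) + work, dtype=settings.dtype)
    h_comb = np.zeros((N_CHANNELS, N_CHANNELS) + resp.otf.shape[2:], dtype=cdt)
    for p in range(resp.n_measurements):
        spec = sp_fft.rfftn(_pad(meas.volumes[p], resp.pad), axes=(-3, -2, -1))
        otf_p = resp.otf[p].astype(cdt)
        data_term += sp_fft.irfftn(
            np.conj(otf_p) * spec.astype(cdt), s=work, axes=(-3, -2, -1)
        ).real.astype(settings.dtype)
        # forward with channel l' then back-project into channel l:
        # H_comb[l, l'] = sum_p conj(OTF_p,l) OTF_p,l'
        for i in range(N_CHANNELS):  # row-wise to bound temporaries
            h_comb[i] += np.conj(otf_p[i])[None] * otf_p
    return EGRLOperators(data_term, h_comb, work, resp.pad, resp.voxel_size)


def _fbp(E: np.ndarray, ops: EGRLOperators) -> np.ndarray:
    """Direct object-to-object transform: IFFT( H_comb(nu) @ E(nu) )."""
    spec = sp_fft.rfftn(E, axes=(-3, -2, -1)).astype(ops.h_comb.dtype)
    out = np.empty_like(spec)
    for i in range(N_CHANNELS):  # keeps peak memory at one channel's worth
        np.sum(ops.h_comb[i] * spec, axis=0, out=out[i])
    return sp_fft.irfftn(out, s=ops.work_shape, axes=(-3, -2, -1)).real.astype(E.dtype)


def _divide_update(
    E: np.ndarray,
    num: np.ndarray,
    den: np.ndarray,
    G: GauntTensor,
    ridge: float,
    freeze_rel: float,
    chunk: int = 262144,
) -> np.ndarray:
    """DV + Update steps on flattened fields (15, n): solve the per-voxel
    Gaunt system M(den) x = num, freeze degenerate voxels, and return the
    Gaunt product of E with the error map x.  Chunked over voxels to bound
    the (n, 15, 15) temporaries."""
    n = E.shape[1]
    dt = E.dtype
    Gm = G.values.reshape(N_CHANNELS, -1).astype(dt)  # (15, 225)
    unit = unit_odf_coeffs().astype(dt)
    # voxel-major copies keep the per-voxel work on contiguous memory
    Ev = np.ascontiguousarray(E.T)
    numv = np.ascontiguousarray(num.T)
    denv = np.ascontiguousarray(den.T)
    thresh = freeze_rel * max(float(den[0].max()), _EPS)
    out = np.empty_like(Ev)
    if _dv_update_kernel is not None:
        gi, gj, gk, gv = _gaunt_sparse(G)
        _dv_update_kernel(
            Ev, numv, denv, gi, gj, gk, gv.astype(dt), float(ridge), thresh, unit, out
        )
        return np.ascontiguousarray(out.T)
    for s in range(0, n, chunk):
        sl = slice(s, min(s + chunk, n))
        m = sl.stop - sl.start
        # ---- DV: error map from the per-voxel Gaunt system M(den) x = num
        M = (denv[sl] @ Gm).reshape(m, N_CHANNELS, N_CHANNELS)
        rhs = numv[sl].copy()
        if ridge:
            # shrink the error map toward the unit function (no update):
            # M @ unit = den, so exact fixed points stay exact at any ridge
            tr = np.trace(M, axis1=-2, axis2=-1) / N_CHANNELS
            lam = ridge * np.abs(tr)
            M[:, np.arange(N_CHANNELS), np.arange(N_CHANNELS)] += lam[:, None]
            rhs += lam[:, None] * unit
        frozen = denv[sl, 0] <= thresh
        M[frozen] = np.eye(N_CHANNELS, dtype=dt)
        rhs[frozen] = unit
        err = _batched_solve(M, rhs)  # (m, 15)
        err[frozen] = unit
        bad = ~np.isfinite(err).all(axis=1)
        if np.any(bad):
            err[bad] = unit
        # ---- Update: Gaunt product of E with the error map,
        # out_k = sum_i E_i (sum_j G_ijk err_j), one GEMM + a reduction
        W = (err @ Gm).reshape(m, N_CHANNELS, N_CHANNELS)  # (m, i, k)
        W *= Ev[sl][:, :, None]
        out[sl] = W.sum(axis=1)
    return np.ascontiguousarray(out.T)


def egrl_iterate(
    E: np.ndarray,
    ops: EGRLOperators,
    G: GauntTensor,
    settings: ReconstructionSettings,
) -> np.ndarray:
    """One eGRL iteration on the working grid: FBP, DV, Update."""
    den = _fbp(E, ops)
    flat = E.reshape(N_CHANNELS, -1)
    out = _divide_update(
        flat,
        ops.data_term.reshape(N_CHANNELS, -1),
        den.reshape(N_CHANNELS, -1),
        G,
        settings.dv_ridge,
        settings.freeze_rel,
    )
    return out.reshape(E.shape)


def _init_estimate(
    sets: list[MeasurementSet], pad: int, work: tuple[int, int, int], dtype
) -> np.ndarray:
    """Uniform angular distribution with density = summed raw data (all
    polarizations, all views)."""
    E0 = np.zeros((N_CHANNELS,) + work, dtype=dtype)
    for meas in sets:
        E0[0] += _pad(meas.volumes.sum(axis=0), pad).astype(dtype)
    return E0


def egrl_reconstruct(
    meas: MeasurementSet,
    resp: SystemResponse,
    settings: ReconstructionSettings | None = None,
    G: GauntTensor | None = None,
    init: SHField | None = None,
) -> SHField:
    """Single-view eGRL deconvolution (default 20 iterations)."""
    settings = settings or ReconstructionSettings()
    G = G or gaunt_tensor()
    ops = egrl_precompute(meas, resp, settings)
    if init is not None:
        E = _pad(init.coeffs, resp.pad).astype(settings.dtype)
    else:
        E = _init_estimate([meas], resp.pad, ops.work_shape, settings.dtype)
    for k in range(settings.n_iter(dual_view=False)):
        E_new = egrl_iterate(E, ops, G, settings)
        rel = np.linalg.norm(E_new - E) / max(np.linalg.norm(E), _EPS)
        logger.info("eGRL iteration %d: relative change %.3e", k + 1, rel)
        E = E_new
    out = _crop(E, resp.pad).astype(float)
    return SHField(out, resp.voxel_size).clamp_density()


def egrl_dualview(
    meas_a: MeasurementSet,
    meas_b: MeasurementSet,
    resp_a: SystemResponse,
    resp_b: SystemResponse,
    settings: ReconstructionSettings | None = None,
    G: GauntTensor | None = None,
    init: SHField | None = None,
) -> SHField:
    """Alternating dual-view eGRL (default 10 full A+B cycles)."""
    settings = settings or ReconstructionSettings()
    G = G or gaunt_tensor()
    if resp_a.shape != resp_b.shape or resp_a.pad != resp_b.pad:
        raise ValueError("the two views must be co-registered on a common grid")
    ops_a = egrl_precompute(meas_a, resp_a, settings)
    ops_b = egrl_precompute(meas_b, resp_b, settings)
    if init is not None:
        E = _pad(init.coeffs, resp_a.pad).astype(settings.dtype)
    else:
        E = _init_estimate([meas_a, meas_b], resp_a.pad, ops_a.work_shape, settings.dtype)
    for k in range(settings.n_iter(dual_view=True)):
        E = egrl_iterate(E, ops_a, G, settings)
        E = egrl_iterate(E, ops_b, G, settings)
        logger.info("dual-view eGRL cycle %d done", k + 1)
    out = _crop(E, resp_a.pad).astype(float)
    return SHField(out, resp_a.voxel_size).clamp_density()


# =====================================================================
# scalar Richardson-Lucy (density baseline)
# =====================================================================
def rl_deconvolve(
    data: np.ndarray,
    psf: np.ndarray,
    iterations: int = 20,
    pad: int = 0,
    variant: str = "classic",
    init: np.ndarray | None = None,
) -> np.ndarray:
    """Scalar Richardson-Lucy deconvolution with a matched back projector.

    ``variant='classic'`` divides in measurement space (the traditional RL
    update); ``variant='restructured'`` back-projects first and divides in
    object space (the scalar limit of the eGRL loop ordering).  The PSF is
    normalized to unit sum; ``pad`` adds a zero margin for linear convolution.
    """
    if variant not in ("classic", "restructured"):
        raise ValueError(f"unknown RL variant {variant!r}")
    psf = psf / psf.sum()
    work = tuple(s + 2 * pad for s in data.shape)
    psf_w = _embed_center(psf, work)
    otf = sp_fft.rfftn(np.fft.ifftshift(psf_w))
    d = _pad(data, pad)
    e = _pad(init, pad) if init is not None else np.full(work, max(d.mean(), _EPS))
    conv = lambda vol, k: sp_fft.irfftn(k * sp_fft.rfftn(vol), s=work)
    if variant == "restructured":
        num = conv(d, np.conj(otf))
    for _ in range(iterations):
        fwd = conv(e, otf)
        if variant == "classic":
            e = e * conv(d / np.maximum(fwd, _EPS), np.conj(otf))
        else:
            den = conv(fwd, np.conj(otf))
            e = e * num / np.maximum(den, _EPS)
    return _crop(e, pad)


def _embed_center(kernel: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Center a (possibly smaller) centered kernel in a larger volume."""
    if kernel.shape == tuple(shape):
        return kernel
    out = np.zeros(shape, dtype=kernel.dtype)
    starts = [ws // 2 - ks // 2 for ws, ks in zip(shape, kernel.shape)]
    sl = tuple(slice(s, s + k) for s, k in zip(starts, kernel.shape))
    out[sl] = kernel
    return out


def rl_dualview(
    data_a: np.ndarray,
    data_b: np.ndarray,
    psf_a: np.ndarray,
    psf_b: np.ndarray,
    iterations: int = 10,
    pad: int = 0,
    variant: str = "classic",
) -> np.ndarray:
    """Alternating dual-view scalar RL (one half-step per view per cycle)."""
    psf_a = psf_a / psf_a.sum()
    psf_b = psf_b / psf_b.sum()
    work = tuple(s + 2 * pad for s in data_a.shape)
    otfs = [
        sp_fft.rfftn(np.fft.ifftshift(_embed_center(p, work))) for p in (psf_a, psf_b)
    ]
    ds = [_pad(data_a, pad), _pad(data_b, pad)]
    e = np.full(work, max(ds[0].mean(), _EPS))
    conv = lambda vol, k: sp_fft.irfftn(k * sp_fft.rfftn(vol), s=work)
    for _ in range(iterations):
        for d, otf in zip(ds, otfs):
            if variant == "classic":
                e = e * conv(d / np.maximum(conv(e, otf), _EPS), np.conj(otf))
            else:
                num = conv(d, np.conj(otf))
                den = conv(conv(e, otf), np.conj(otf))
                e = e * num / np.maximum(den, _EPS)
    return _crop(e, pad)


def density_psf(resp: SystemResponse) -> np.ndarray:
    """Orientation-averaged scalar PSF of a response (mean over modulations)."""
    return resp.psf[:, 0].mean(axis=0)


# =====================================================================
# dense GRL baseline (and the dense eGRL oracle)
# =====================================================================
class ResourceGuardError(RuntimeError):
    """Raised when the dense GRL is asked for a grid it should not attempt."""


def grl_reconstruct(
    meas: MeasurementSet,
    resp: SystemResponse,
    settings: ReconstructionSettings | None = None,
    grid: SphereGrid | None = None,
    variant: str = "mlem",
    init: SHField | None = None,
    max_grid: int = 32,
    override_guard: bool = False,
    return_loglik: bool = False,
):
    """Dense spatio-angular GRL: MLEM over (voxel x direction) samples.

    ``variant='mlem'`` is the baseline update (divide in measurement space,
    normalize by the object-space sensitivity); its Poisson log-likelihood is
    non-decreasing.  ``variant='restructured'`` reorders the steps exactly as
    eGRL does (back-project, ODF-divide in object space, multiply) and is the
    dense oracle the spherical-harmonics implementation is validated against.
    Guarded to grids <= ``max_grid`` per axis unless overridden.
    """
    settings = settings or ReconstructionSettings()
    if variant not in ("mlem", "restructured"):
        raise ValueError(f"unknown GRL variant {variant!r}")
    if max(resp.shape) > max_grid and not override_guard:
        raise ResourceGuardError(
            f"dense GRL on {resp.shape} exceeds the {max_grid}^3 guard; "
            "pass override_guard=True to proceed"
        )
    grid = grid or SphereGrid.for_band(12)
    work = resp.work_shape
    Y = basis_matrix(grid)  # (15, O)
    w = grid.weights
    # dense per-direction OTFs, h_p(., s_o) in Fourier space
    otfd = np.einsum("pc...,co->po...", resp.otf, Y, optimize=True)
    data_spec = np.stack(
        [sp_fft.rfftn(_pad(v, resp.pad)) for v in meas.volumes]
    )
    if init is not None:
        e = np.tensordot(Y, _pad(init.coeffs, resp.pad), axes=(0, 0))
    else:
        # uniform angular distribution with F00 = summed data: samples F00 * Y00
        dens = sum(_pad(v, resp.pad) for v in meas.volumes)
        e = np.broadcast_to(dens * Y[0, 0], (grid.count,) + work).copy()
    sens = np.einsum("po->o", otfd[..., 0, 0, 0].real)  # sum_p sum_r h_p(r, s_o)
    # orientations in the acquisition null space (e.g. dipoles along a single
    # view's illumination axis) have ~zero sensitivity; the relative floor
    # keeps their updates finite and decaying instead of 0/0
    sens = np.maximum(sens, 1e-12 * sens.max())
    logliks = []
    if variant == "restructured":
        num = np.einsum(
            "po...,p...->o...", np.conj(otfd), data_spec, optimize=True
        )
        num = sp_fft.irfftn(num, s=work, axes=(-3, -2, -1)).real
        Mw = Y * w  # (15, O)
    n_iter = settings.n_iter(dual_view=False)
    for _ in range(n_iter):
        e_spec = sp_fft.rfftn(e, axes=(-3, -2, -1))
        fwd_spec = np.einsum("po...,o,o...->p...", otfd, w, e_spec, optimize=True)
        fwd = sp_fft.irfftn(fwd_spec, s=work, axes=(-3, -2, -1)).real
        np.maximum(fwd, 0.0, out=fwd)
        if return_loglik:
            data = np.stack([_pad(v, resp.pad) for v in meas.volumes])
            logliks.append(float(np.sum(data * np.log(fwd + 1e-12) - fwd)))
        if variant == "mlem":
            ratio = np.stack([_pad(v, resp.pad) for v in meas.volumes]) / np.maximum(
                fwd, _EPS
            )
            ratio_spec = sp_fft.rfftn(ratio, axes=(-3, -2, -1))
            back = np.einsum(
                "po...,p...->o...", np.conj(otfd), ratio_spec, optimize=True
            )
            back = sp_fft.irfftn(back, s=work, axes=(-3, -2, -1)).real
            e = e * back / sens[:, None, None, None]
        else:
            den = np.einsum(
                "po...,p...->o...", np.conj(otfd), sp_fft.rfftn(fwd, axes=(-3, -2, -1)),
                optimize=True,
            )
            den = sp_fft.irfftn(den, s=work, axes=(-3, -2, -1)).real
            e = _dense_divide_update(e, num, den, Y, w, settings)
    coeffs = np.tensordot(Y * w, e, axes=(1, 0))
    out = SHField(_crop(coeffs, resp.pad).astype(float), resp.voxel_size).clamp_density()
    if return_loglik:
        return out, np.array(logliks)
    return out


def _dense_divide_update(
    e: np.ndarray,
    num: np.ndarray,
    den: np.ndarray,
    Y: np.ndarray,
    w: np.ndarray,
    settings: ReconstructionSettings,
) -> np.ndarray:
    """Dense-domain DV + Update: per-voxel weighted Galerkin division of the
    sampled ODFs onto the band, then band-limited product with the estimate.
    Mirrors the spherical-harmonics path exactly when the grid quadrature is
    exact for the integrands."""
    O = e.shape[0]
    nflat = int(np.prod(e.shape[1:]))
    ef = e.reshape(O, nflat)
    numf = num.reshape(O, nflat)
    denf = den.reshape(O, nflat)
    Yw = Y * w  # (15, O)
    # per-voxel normal matrices M[v] = Y W diag(den[:, v]) Y^T
    M = np.einsum("io,jo,ov->vij", Yw, Y, denf, optimize=True)
    rhs = (Yw @ numf).T  # (v, 15)
    unit = unit_odf_coeffs()
    if settings.dv_ridge:
        # shrink toward the unit error map, mirroring the SH-domain path
        tr = np.trace(M, axis1=-2, axis2=-1) / N_CHANNELS
        lam = settings.dv_ridge * np.abs(tr)
        M[:, np.arange(N_CHANNELS), np.arange(N_CHANNELS)] += lam[:, None]
        rhs += lam[:, None] * unit
    den_rho = (Yw @ denf)[0]
    frozen = den_rho <= settings.freeze_rel * max(den_rho.max(), _EPS)
    M[frozen] = np.eye(N_CHANNELS)
    rhs[frozen] = unit
    x = np.linalg.solve(M, rhs[..., None])[..., 0]
    x[frozen] = unit
    err = Y.T @ x.T  # sampled error map (O, v)
    prod = ef * err
    coeffs = Yw @ prod  # band-limited projection of the product
    return (Y.T @ coeffs).reshape(e.shape)


def poisson_loglik(meas: MeasurementSet, model: MeasurementSet) -> float:
    """Poisson log-likelihood sum(i log f - f) of data under a noise-free model."""
    f = model.volumes
    return float(np.sum(meas.volumes * np.log(f + 1e-12) - f))


# =====================================================================
# eGRL-p ablation
# =====================================================================
def egrlp_reconstruct(
    meas: MeasurementSet,
    resp: SystemResponse,
    settings: ReconstructionSettings | None = None,
    G: GauntTensor | None = None,
) -> SHField:
    """Decoupled density/orientation estimation (the eGRL-p ablation).

    Stage 1 deconvolves each polarization channel independently with scalar
    RL; stage 2 runs the per-voxel angular iteration with spatially
    integrated responses (voxels treated as independent).
    """
    settings = settings or ReconstructionSettings()
    G = G or gaunt_tensor()
    n_iter = settings.n_iter(dual_view=False)
    decon = np.stack(
        [
            rl_deconvolve(
                meas.volumes[p],
                np.maximum(resp.psf[p, 0], 0.0),
                iterations=n_iter,
                pad=resp.pad,
            )
            for p in range(resp.n_measurements)
        ]
    )
    a = resp.psf.sum(axis=(2, 3, 4))  # (P, 15) spatially integrated responses
    flat = decon.reshape(resp.n_measurements, -1)
    data_term = a.T @ flat  # (15, n)
    h_comb = a.T @ a  # (15, 15)
    E = np.zeros_like(data_term)
    E[0] = flat.sum(axis=0)
    for _ in range(n_iter):
        den = h_comb @ E
        E = _divide_update(E, data_term, den, G, settings.dv_ridge, settings.freeze_rel)
    coeffs = E.reshape((N_CHANNELS,) + meas.volumes.shape[1:])
    return SHField(coeffs.astype(float), resp.voxel_size).clamp_density()


# =====================================================================
# SVD / Tikhonov baseline
# =====================================================================
@dataclass
class SVDSystem:
    """Per-frequency SVD factors of the (measurements x 15) transfer matrix."""

    u: np.ndarray = field(repr=False)  # (nfreq, P, R) polarization-side
    s: np.ndarray = field(repr=False)  # (nfreq, R) singular values, descending
    vh: np.ndarray = field(repr=False)  # (nfreq, R, 15) SH-side
    proj: np.ndarray = field(repr=False)  # (nfreq, R) = u^H I(nu)
    work_shape: tuple[int, int, int]
    pad: int
    voxel_size: float

    @property
    def rank(self) -> int:
        return self.s.shape[-1]


def svd_factorize(
    sets: list[MeasurementSet], resps: list[SystemResponse], chunk: int = 65536
) -> SVDSystem:
    """Factorize the concatenated (dual-view) transfer matrix per frequency.

    Views are concatenated along the polarization channel, as the dual-view
    Tikhonov formulation requires; rank R = min(total measurements, 15).
    """
    resp0 = resps[0]
    work = resp0.work_shape
    otf = np.concatenate([r.otf for r in resps], axis=0)  # (Ptot, 15, freq)
    data_spec = np.concatenate(
        [
            np.stack([sp_fft.rfftn(_pad(v, r.pad)) for v in m.volumes])
            for m, r in zip(sets, resps)
        ]
    )
    Ptot = otf.shape[0]
    nf = int(np.prod(otf.shape[2:]))
    A = otf.reshape(Ptot, N_CHANNELS, nf)
    I = data_spec.reshape(Ptot, nf)
    R = min(Ptot, N_CHANNELS)
    u = np.empty((nf, Ptot, R), dtype=complex)
    s = np.empty((nf, R))
    vh = np.empty((nf, R, N_CHANNELS), dtype=complex)
    proj = np.empty((nf, R), dtype=complex)
    for start in range(0, nf, chunk):
        sl = slice(start, min(start + chunk, nf))
        Ab = np.moveaxis(A[:, :, sl], -1, 0)  # (b, P, 15)
        ub, sb, vhb = np.linalg.svd(Ab, full_matrices=False)
        u[sl], s[sl], vh[sl] = ub, sb, vhb
        proj[sl] = np.einsum("bpk,pb->bk", np.conj(ub), I[:, sl])
    return SVDSystem(u, s, vh, proj, work, resp0.pad, resp0.voxel_size)


def svd_apply(system: SVDSystem, eta: float) -> SHField:
    """Tikhonov combination F_lm = sum_k mu/(mu^2+eta) U_k,lm (V_k . I)."""
    if eta < 0:
        raise ValueError("eta must be nonnegative")
    filt = system.s / (system.s**2 + eta)
    F = np.einsum("bk,bkc->cb", filt * system.proj, np.conj(system.vh), optimize=True)
    wz, wy, wx = system.work_shape
    F = F.reshape((N_CHANNELS, wz, wy, wx // 2 + 1))
    vols = sp_fft.irfftn(F, s=system.work_shape, axes=(-3, -2, -1)).real
    return SHField(_crop(vols, system.pad), system.voxel_size)


def svd_reconstruct(
    sets: MeasurementSet | list[MeasurementSet],
    resps: SystemResponse | list[SystemResponse],
    settings: ReconstructionSettings | None = None,
    eta: float | None = None,
) -> SHField:
    """Per-frequency Tikhonov pseudoinverse reconstruction (SVD baseline)."""
    settings = settings or ReconstructionSettings()
    if isinstance(sets, MeasurementSet):
        sets, resps = [sets], [resps]
    system = svd_factorize(sets, resps)
    return svd_apply(system, settings.eta if eta is None else eta)


def svd_eta_search(
    sets: MeasurementSet | list[MeasurementSet],
    resps: SystemResponse | list[SystemResponse],
    truth: SHField,
    settings: ReconstructionSettings | None = None,
    grid: SphereGrid | None = None,
) -> tuple[float, np.ndarray]:
    """Pick eta on the settings grid by maximizing PSIM against ground truth.

    Returns (eta_best, table) where table rows are (eta, psim).
    """
    from .metrics import psim, support_mask
    from .odf_maps import peak_orientation

    settings = settings or ReconstructionSettings()
    grid = grid or SphereGrid.fibonacci(1000)
    if isinstance(sets, MeasurementSet):
        sets, resps = [sets], [resps]
    system = svd_factorize(sets, resps)
    mask = support_mask(truth.density)
    peaks_gt = peak_orientation(truth, grid, mask=mask)
    rows = []
    for eta in settings.eta_grid:
        est = svd_apply(system, float(eta))
        peaks = peak_orientation(est, grid, mask=mask)
        rows.append((float(eta), psim(peaks_gt, peaks, mask)))
    table = np.array(rows)
    best = table[np.argmax(table[:, 1]), 0]
    return float(best), table
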