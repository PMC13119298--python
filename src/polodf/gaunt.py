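"""Real Gaunt coefficients and ODF algebra in spherical-harmonics space.

The Gaunt tensor G^{l l' l''}_{m m' m''} = int Y_lm Y_l'm' Y_l''m'' dOmega turns
pointwise products and quotients of band-limited ODFs into coefficient-space
contractions, which is what keeps the whole reconstruction anchored in the
15-channel spherical-harmonics domain.  Entries are computed by a
Gauss-Legendre product quadrature that is exact for the polynomial integrands,
so the stored values are exact to float rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sphere import DIPOLE_ORDERS, EVEN_CHANNELS, N_CHANNELS, SphereGrid, basis_matrix


class ConditioningError(np.linalg.LinAlgError):
    """Raised when an ODF division system is singular and no ridge is allowed."""


@dataclass(frozen=True)
class GauntTensor:
    """Dense real Gaunt tensor over the even-degree band l, l', l'' <= l_max.

    ``values[i, j, k]`` is the triple-product integral of channels i, j, k in
    the EVEN_CHANNELS ordering; the tensor is symmetric under any permutation
    of its three indices and vanishes where the selection rules forbid
    coupling.
    """

    l_max: int
    values: np.ndarray = field(repr=False)

    @property
    def channels(self):
        return EVEN_CHANNELS


def _triple_quadrature(channels_a, channels_b, channels_c, degree: int) -> np.ndarray:
    grid = SphereGrid.for_band(degree)
    Ya = basis_matrix(grid, tuple(channels_a))
    Yb = basis_matrix(grid, tuple(channels_b))
    Yc = basis_matrix(grid, tuple(channels_c))
    out = np.einsum("io,jo,ko,o->ijk", Ya, Yb, Yc, grid.weights, optimize=True)
    out[np.abs(out) < 1e-12] = 0.0
    return out


def gaunt_tensor(l_max: int = 4) -> GauntTensor:
    """Real Gaunt tensor for the even band l <= l_max (l_max even, default 4)."""
    if l_max % 2 or l_max < 0 or l_max > 4:
        raise ValueError("l_max must be 0, 2 or 4")
    channels = tuple(c for c in EVEN_CHANNELS if c[0] <= l_max)
    vals = _triple_quadrature(channels, channels, channels, 3 * l_max)
    if l_max < 4:
        # embed into the full 15-channel tensor (higher channels decouple)
        full = np.zeros((N_CHANNELS,) * 3)
        n = len(channels)
        full[:n, :n, :n] = vals
        vals = full
    return GauntTensor(l_max=l_max, values=vals)


def gaunt_dipole_couplings() -> np.ndarray:
    """Couplings G^{l 1 1}_{m eps_j eps_j'} of the dipole detection model.

    Returns an array of shape (15, 3, 3): even-band channel x dipole component
    j x j', with the component order (x, y, z) mapped onto degree-1 orders
    (+1, -1, 0).  Only l in {0, 2} is nonzero (quadratic dipole dependence).
    """
    deg1 = tuple((1, m) for m in DIPOLE_ORDERS)
    return _triple_quadrature(EVEN_CHANNELS, deg1, deg1, 4 + 1 + 1)


def odf_multiply(a: np.ndarray, b: np.ndarray, G: GauntTensor) -> np.ndarray:
    """Band-limited pointwise product of two ODFs in coefficient space.

    Equals the SH analysis of the pointwise product truncated to the band;
    bilinear and commutative, with the unit function as identity.  The channel
    axis is the first axis of both operands.
    """
    return np.einsum("ijk,i...,j...->k...", G.values, a, b, optimize=True)


def division_operator(den: np.ndarray, G: GauntTensor) -> np.ndarray:
    """Multiplication-by-``den`` matrix M_{lm,l'm'} = sum G_{l l' l''} den_{l''}.

    Returns shape (15, 15, ...) matching trailing axes of ``den``.
    """
    return np.einsum("ijk,k...->ij...", G.values, den, optimize=True)


def odf_divide(
    num: np.ndarray,
    den: np.ndarray,
    G: GauntTensor,
    ridge: float = 1e-6,
) -> np.ndarray:
    """Band-limited quotient num/den by solving the Galerkin system M x = num.

    M is the Gaunt contraction of ``den`` (multiplication operator projected
    onto the band).  ``ridge`` adds ``ridge * trace(M)/15`` to the diagonal,
    keeping the conditioning strategy scale invariant; with ridge = 0 a
    singular system raises :class:`ConditioningError`.  Exact inverse of
    :func:`odf_multiply`: ``odf_divide(odf_multiply(a, b), b) == a`` whenever
    M is well conditioned.
    """
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    M = division_operator(den, G)  # (15, 15, ...)
    # move channel axes last for the stacked solver
    M = np.moveaxis(M, (0, 1), (-2, -1))
    rhs = np.moveaxis(num, 0, -1)[..., None]
    if ridge:
        tr = np.trace(M, axis1=-2, axis2=-1) / N_CHANNELS
        # absolute fallback keeps the all-zero denominator finite
        lam = ridge * np.where(np.abs(tr) > 0, np.abs(tr), 1.0)
        M = M + lam[..., None, None] * np.eye(N_CHANNELS)
    try:
        x = np.linalg.solve(M, rhs)
    except np.linalg.LinAlgError as err:
        raise ConditioningError(
            "singular ODF division system; use ridge > 0"
        ) from err
    if not np.all(np.isfinite(x)):
        raise ConditioningError("non-finite ODF division result; use ridge > 0")
    return np.moveaxis(x[..., 0], -1, 0)
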