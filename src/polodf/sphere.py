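"""Direction grids on the unit sphere and the real spherical-harmonics basis.

Every angular quantity in the package (orientation distribution functions,
dipole responses, excitation patterns) lives in a 15-channel real
spherical-harmonics (SH) basis restricted to even degrees l in {0, 2, 4}:
dipole emission intensity is antipodally symmetric, so odd-degree content is
identically zero, and the imaging band limit removes everything above l = 4.

The basis is the orthonormal *real* SH set (cosine harmonics for m > 0, sine
harmonics for m < 0, no Condon-Shortley phase), ordered
(0,0), (2,-2) ... (2,2), (4,-4) ... (4,4).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import sph_harm_y

#: channel table for the even-degree band l <= 4 (15 channels)
EVEN_CHANNELS: tuple[tuple[int, int], ...] = tuple(
    (l, m) for l in (0, 2, 4) for m in range(-l, l + 1)
)

N_CHANNELS = len(EVEN_CHANNELS)  # 15

#: degree-1 channels used by the dipole detection model, ordered to match the
#: dipole-component convention eps_0 = +1 (x), eps_1 = -1 (y), eps_2 = 0 (z)
DIPOLE_ORDERS: tuple[int, ...] = (1, -1, 0)


class InvalidOrderError(ValueError):
    """Raised when |m| > l is requested."""


def real_sph_harm(l: int, m: int, directions: np.ndarray) -> np.ndarray:
    """Evaluate the orthonormal real spherical harmonic Y_lm on unit vectors.

    Parameters
    ----------
    l, m
        Degree and order, ``|m| <= l``.
    directions
        Array of shape (..., 3) of unit vectors (x, y, z).

    Returns
    -------
    Array of shape (...) with the real basis values.  The convention is the
    standard tesseral one without Condon-Shortley phase, e.g.
    Y_{1,1} = sqrt(3/4pi) x,  Y_{1,-1} = sqrt(3/4pi) y,  Y_{1,0} = sqrt(3/4pi) z.
    """
    if abs(m) > l:
        raise InvalidOrderError(f"|m| = {abs(m)} exceeds degree l = {l}")
    d = np.asarray(directions, dtype=float)
    x, y, z = d[..., 0], d[..., 1], d[..., 2]
    theta = np.arccos(np.clip(z, -1.0, 1.0))
    phi = np.arctan2(y, x)
    if m == 0:
        return np.real(sph_harm_y(l, 0, theta, phi))
    ylm = sph_harm_y(l, abs(m), theta, phi)  # includes Condon-Shortley phase
    sign = (-1.0) ** abs(m)  # cancels the Condon-Shortley phase
    if m > 0:
        return np.sqrt(2.0) * sign * np.real(ylm)
    return np.sqrt(2.0) * sign * np.imag(ylm)


@dataclass(frozen=True)
class SphereGrid:
    """Discrete unit directions with quadrature weights (steradians).

    Invariants: all directions are unit vectors, the weights sum to 4*pi, and
    the grid is antipodally balanced so that odd-degree harmonics integrate
    to zero.
    """

    directions: np.ndarray  # (n, 3)
    weights: np.ndarray  # (n,)

    def __post_init__(self) -> None:
        d = np.asarray(self.directions, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if d.ndim != 2 or d.shape[1] != 3 or w.shape != (d.shape[0],):
            raise ValueError("directions must be (n, 3) and weights (n,)")
        norms = np.linalg.norm(d, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-12):
            raise ValueError("directions must be unit vectors")
        if abs(w.sum() - 4.0 * np.pi) > 1e-6:
            raise ValueError("quadrature weights must sum to 4*pi")
        object.__setattr__(self, "directions", d)
        object.__setattr__(self, "weights", w)

    @property
    def count(self) -> int:
        return self.directions.shape[0]

    # ------------------------------------------------------------------ ctors
    @classmethod
    def fibonacci(cls, n: int = 2562) -> "SphereGrid":
        """Near-uniform antipodally symmetric Fibonacci lattice.

        ``n`` is rounded down to an even count; points are generated on the
        upper hemisphere by the golden-angle spiral and mirrored, so the grid
        is exactly antipodally balanced.  Weights are equal (4*pi / n).
        """
        half = max(1, n // 2)
        i = np.arange(half) + 0.5
        z = i / half  # (0, 1]
        golden = np.pi * (3.0 - np.sqrt(5.0))
        phi = golden * np.arange(half)
        r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
        upper = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
        dirs = np.vstack([upper, -upper])
        w = np.full(dirs.shape[0], 4.0 * np.pi / dirs.shape[0])
        return cls(dirs, w)

    @classmethod
    def gauss_legendre(cls, n_theta: int, n_phi: int) -> "SphereGrid":
        """Gauss-Legendre x uniform-azimuth product grid.

        Integrates spherical polynomials exactly up to degree
        min(2*n_theta - 1, n_phi - 1).  Antipodally balanced by construction
        (the Legendre node set is symmetric and n_phi uniform azimuths wrap).
        """
        nodes, wts = np.polynomial.legendre.leggauss(n_theta)
        phi = 2.0 * np.pi * np.arange(n_phi) / n_phi
        ct, ph = np.meshgrid(nodes, phi, indexing="ij")
        st = np.sqrt(1.0 - ct**2)
        dirs = np.column_stack(
            [(st * np.cos(ph)).ravel(), (st * np.sin(ph)).ravel(), ct.ravel()]
        )
        w = np.repeat(wts, n_phi) * (2.0 * np.pi / n_phi)
        return cls(dirs, w)

    @classmethod
    def for_band(cls, degree: int) -> "SphereGrid":
        """Smallest product grid exact for spherical polynomials <= ``degree``."""
        n_theta = degree // 2 + 1
        n_phi = degree + 1
        return cls.gauss_legendre(n_theta, n_phi)


def basis_matrix(
    grid: SphereGrid, channels: tuple[tuple[int, int], ...] = EVEN_CHANNELS
) -> np.ndarray:
    """Matrix Y of shape (n_channels, n_directions): Y[c, o] = Y_c(s_o)."""
    return np.stack([real_sph_harm(l, m, grid.directions) for l, m in channels])


class ResolutionError(ValueError):
    """Raised when a grid cannot resolve the requested band limit."""


def _check_resolving(grid: SphereGrid, degree: int) -> None:
    # a grid exact for products of two band-limited functions must at least
    # hold one sample per basis function
    n_basis = sum(2 * l + 1 for l in range(0, degree + 1, 2))
    if grid.count < n_basis:
        raise ResolutionError(
            f"grid with {grid.count} directions cannot resolve band l <= {degree}"
        )


def sh_synthesize(coeffs: np.ndarray, grid: SphereGrid) -> np.ndarray:
    """Sample band-limited ODFs on a direction grid.

    ``coeffs`` has the 15 channels on the *first* axis, any shape after;
    returns an array with the channel axis replaced by the direction axis.
    """
    coeffs = np.asarray(coeffs)
    if coeffs.shape[0] != N_CHANNELS:
        raise ValueError(f"expected {N_CHANNELS} channels, got {coeffs.shape[0]}")
    Y = basis_matrix(grid)
    return np.tensordot(Y, coeffs, axes=(0, 0))


def sh_analyze(samples: np.ndarray, grid: SphereGrid) -> np.ndarray:
    """Project direction samples onto the 15-channel even band by quadrature.

    Exact (analyze o synthesize = identity) whenever the grid quadrature is
    exact for degree 2*l_max = 8, e.g. ``SphereGrid.for_band(8)`` or finer.
    """
    samples = np.asarray(samples)
    _check_resolving(grid, 4)
    Y = basis_matrix(grid)
    return np.tensordot(Y * grid.weights, samples, axes=(1, 0))


def unit_odf_coeffs() -> np.ndarray:
    """Coefficients of the constant unit function on the sphere: (0,0) = 2*sqrt(pi)."""
    c = np.zeros(N_CHANNELS)
    c[0] = 2.0 * np.sqrt(np.pi)
    return c
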