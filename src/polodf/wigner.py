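"""Real Wigner blocks for the 90-degree view change of a dual-view microscope.

The second detection arm of a diSPIM looks along x instead of z.  On the even
spherical-harmonics band this change of view is the coefficient transform of
the orthogonal direction map that exchanges x and z (on even degrees it is
identical to a proper 180-degree rotation about (x+z)/sqrt(2), because point
inversion acts trivially there).  The l = 2 block of this transform is

    [[0, 1, 0,    0,  0,        0],      (rows/cols: (2,-2)...(2,2))
     [1, 0, 0,    0,  0,        0],
     [0, 0, -1/2, 0,  sqrt3/2,  0], ...]

Blocks are computed by exact quadrature rather than hard-coded, and each block
is orthogonal and involutive (applying the view change twice is the identity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sphere import EVEN_CHANNELS, N_CHANNELS, SphereGrid, basis_matrix


def _swap_xz(directions: np.ndarray) -> np.ndarray:
    return directions[..., [2, 1, 0]]


@dataclass(frozen=True)
class WignerRotation:
    """Per-degree real coefficient-transform blocks for a view change.

    ``blocks[l]`` is the (2l+1) x (2l+1) orthogonal matrix acting on the
    order index; ``matrix`` is the block-diagonal 15 x 15 form over the even
    band.  The l = 0 block is always [1].
    """

    blocks: dict[int, np.ndarray] = field(repr=False)

    @property
    def matrix(self) -> np.ndarray:
        out = np.zeros((N_CHANNELS, N_CHANNELS))
        start = 0
        for l in (0, 2, 4):
            n = 2 * l + 1
            out[start : start + n, start : start + n] = self.blocks[l]
            start += n
        return out

    def apply(self, coeffs: np.ndarray) -> np.ndarray:
        """Transform a 15-channel coefficient array (channel axis first)."""
        return np.tensordot(self.matrix, coeffs, axes=(1, 0))


def wigner_y90(l_max: int = 4) -> WignerRotation:
    """Coefficient transform mapping the view-A frame (axis z) onto view B (axis x).

    Computed as Delta[j, i] = int Y_j(s) Y_i(T s) dOmega with T the x<->z
    exchange, using a quadrature exact for the integrands, so entries are
    exact to float rounding.  Reproduces the printed dual-view 6 x 6 matrix on
    l <= 2.
    """
    if l_max < 2:
        raise ValueError("l_max must be >= 2")
    from .sphere import real_sph_harm

    grid = SphereGrid.for_band(2 * 4)
    Y = basis_matrix(grid)
    swapped = _swap_xz(grid.directions)
    Ys = np.stack([real_sph_harm(l, m, swapped) for l, m in EVEN_CHANNELS])
    full = np.einsum("jo,io,o->ji", Y, Ys, grid.weights)
    full[np.abs(full) < 1e-12] = 0.0
    blocks = {}
    start = 0
    for l in (0, 2, 4):
        n = 2 * l + 1
        blocks[l] = full[start : start + n, start : start + n]
        start += n
    return WignerRotation(blocks=blocks)


def rotate_field_y90(coeffs: np.ndarray, rotation: WignerRotation) -> np.ndarray:
    """Apply the view change to a whole SH field: spatial x<->z axis swap plus
    per-voxel coefficient mixing.

    ``coeffs`` is (15, nz, ny, nx) in (z, y, x) array order; the spatial part
    of the map is an exact axis transpose (no interpolation).
    """
    swapped = np.swapaxes(coeffs, 1, 3)
    return rotation.apply(swapped)
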