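"""The SHField container: a voxel grid of orientation distribution functions."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sphere import N_CHANNELS


@dataclass
class SHField:
    """A 3D grid whose every voxel carries the 15 even-degree real SH
    coefficients of its orientation distribution function.

    ``coeffs`` is (15, nz, ny, nx) in (z, y, x) array order; ``voxel_size`` is
    the isotropic voxel edge in nm.  Channel 0 is the density channel F_{0,0}.
    """

    coeffs: np.ndarray = field(repr=False)
    voxel_size: float = 130.0

    def __post_init__(self) -> None:
        c = np.asarray(self.coeffs)
        if c.ndim != 4 or c.shape[0] != N_CHANNELS:
            raise ValueError(
                f"coeffs must be ({N_CHANNELS}, nz, ny, nx); got {c.shape}"
            )
        if not np.all(np.isfinite(c)):
            raise ValueError("coefficients must be finite")
        self.coeffs = c

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.coeffs.shape[1:]

    @property
    def density(self) -> np.ndarray:
        return self.coeffs[0]

    def copy(self) -> "SHField":
        return SHField(self.coeffs.copy(), self.voxel_size)

    def clamp_density(self, rel_tol: float = 1e-6) -> "SHField":
        """Zero small negative densities (numerical residue); flag larger ones.

        Negative F_{0,0} above ``-rel_tol * max`` is clipped to 0; anything
        more negative indicates a genuine violation and raises.
        """
        rho = self.coeffs[0]
        peak = float(rho.max()) if rho.size else 0.0
        floor = -rel_tol * max(peak, np.finfo(float).tiny)
        out = self.coeffs.copy()
        bad = rho < floor
        if np.any(bad):
            # genuine violations are clamped too, but reported
            import warnings

            warnings.warn(
                f"{int(bad.sum())} voxels violate non-negativity beyond tolerance",
                RuntimeWarning,
                stacklevel=2,
            )
        out[0] = np.maximum(rho, 0.0)
        out[1:, out[0] == 0.0] = 0.0
        return SHField(out, self.voxel_size)
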