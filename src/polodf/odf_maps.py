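"""Per-voxel ODF statistics: density, peak/principal orientation, GFA, OP.

Orientations of fluorescent dipoles are axes, not signed vectors; all
orientation maps are canonicalized to the z >= 0 (then y >= 0, then x >= 0)
hemisphere and reported as unit vectors (zero vector where the voxel is
empty).
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import distance_transform_edt

from .field import SHField
from .sphere import EVEN_CHANNELS, SphereGrid, basis_matrix, real_sph_harm

_L2 = slice(1, 6)  # the five l = 2 channels


def density_map(field: SHField) -> np.ndarray:
    """Orientation-independent spatial density rho(r) = F_{0,0}(r)."""
    return field.coeffs[0].copy()


def canonicalize_axes(vecs: np.ndarray) -> np.ndarray:
    """Map unit axes into the z >= 0 (then y >= 0, then x >= 0) hemisphere.

    ``vecs`` is (..., 3) in (x, y, z) component order.
    """
    v = np.array(vecs, dtype=float)
    flip = (v[..., 2] < 0) | (
        (v[..., 2] == 0) & ((v[..., 1] < 0) | ((v[..., 1] == 0) & (v[..., 0] < 0)))
    )
    v[flip] *= -1.0
    return v


def _refine_directions(
    coeffs: np.ndarray, best: np.ndarray, spacing: float, rounds: int = 2, k: int = 5
) -> np.ndarray:
    """Local argmax refinement: resample a shrinking cap of directions around
    the current best direction of each voxel."""
    n = best.shape[0]
    for _ in range(rounds):
        # tangent frames
        up = np.where(np.abs(best[:, 2:3]) < 0.9, [[0.0, 0.0, 1.0]], [[1.0, 0.0, 0.0]])
        t1 = np.cross(best, up)
        t1 /= np.linalg.norm(t1, axis=1, keepdims=True)
        t2 = np.cross(best, t1)
        offs = np.linspace(-spacing, spacing, k)
        da, db = np.meshgrid(offs, offs, indexing="ij")
        da, db = da.ravel(), db.ravel()  # (k*k,)
        cand = (
            best[:, None, :]
            + da[None, :, None] * t1[:, None, :]
            + db[None, :, None] * t2[:, None, :]
        )
        cand /= np.linalg.norm(cand, axis=2, keepdims=True)
        # evaluate the SH series on per-voxel candidate sets
        Y = np.stack(
            [real_sph_harm(l, m, cand) for (l, m) in EVEN_CHANNELS]
        )  # (15, n, k*k)
        vals = np.einsum("cv,cvq->vq", coeffs, Y, optimize=True)
        best = cand[np.arange(n), np.argmax(vals, axis=1)]
        spacing /= max(k - 1, 2) / 2.0
    return best


def peak_orientation(
    field: SHField,
    grid: SphereGrid,
    mask: np.ndarray | None = None,
    refine: bool = True,
    chunk: int = 20000,
) -> np.ndarray:
    """Most probable dipole axis per voxel: argmax of the synthesized ODF.

    Grid ties break toward the lowest direction index; a local refinement
    (default on) sharpens the argmax well below the grid spacing.  Returns
    (nz, ny, nx, 3) unit axes, zero vectors at empty (or unmasked) voxels.
    """
    coeffs = field.coeffs.reshape(15, -1)
    nvox = coeffs.shape[1]
    if mask is None:
        mask = np.any(field.coeffs != 0, axis=0)
    sel = np.flatnonzero(mask.ravel())
    Y = basis_matrix(grid)  # (15, O)
    spacing = np.sqrt(4.0 * np.pi / grid.count)
    out = np.zeros((nvox, 3))
    for start in range(0, sel.size, chunk):
        idx = sel[start : start + chunk]
        c = coeffs[:, idx]
        vals = c.T @ Y  # (v, O)
        best = grid.directions[np.argmax(vals, axis=1)]
        if refine:
            best = _refine_directions(c, best, spacing)
        out[idx] = canonicalize_axes(best)
    return out.reshape(field.shape + (3,))


def principal_orientation(
    field: SHField,
    grid: SphereGrid,
    mask: np.ndarray | None = None,
    chunk: int = 4000,
) -> np.ndarray:
    """Maximum-projection axis: argmax_s sum_s' |s.s'| f(r, s'), quadrature
    weighted — the overall alignment axis of the ODF, robust to multiple
    lobes.  Degenerate (isotropic) voxels return the canonical tie-break
    direction (lowest grid index)."""
    coeffs = field.coeffs.reshape(15, -1)
    nvox = coeffs.shape[1]
    if mask is None:
        mask = np.any(field.coeffs != 0, axis=0)
    sel = np.flatnonzero(mask.ravel())
    Y = basis_matrix(grid)
    T = np.abs(grid.directions @ grid.directions.T) * grid.weights[None, :]  # (C, O)
    out = np.zeros((nvox, 3))
    for start in range(0, sel.size, chunk):
        idx = sel[start : start + chunk]
        f = (coeffs[:, idx].T @ Y).T  # samples (O, v)
        scores = T @ f  # (C, v)
        out[idx] = canonicalize_axes(grid.directions[np.argmax(scores, axis=0)])
    return out.reshape(field.shape + (3,))


def gfa_map(field: SHField) -> np.ndarray:
    """Generalized fractional anisotropy sqrt(1 - F00^2 / sum F_lm^2) in [0, 1)."""
    power = np.sum(field.coeffs**2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.sqrt(np.clip(1.0 - field.coeffs[0] ** 2 / power, 0.0, None))
    g[power == 0] = 0.0
    return g


def op_map(field: SHField, n_hat: np.ndarray) -> np.ndarray:
    """Order parameter <P2(s.n)> of each voxel's ODF about the axis n.

    Built from the l = 2 channels only: OP = (2 sqrt(pi)/5) (1/F00)
    sum_m F_2m Y_2m(n); ranges over [-1/2, 1] (1 = perfectly aligned with n,
    -1/2 = confined to the plane normal to n, 0 = isotropic).  NaN where the
    density vanishes.
    """
    n_hat = np.asarray(n_hat, dtype=float)
    if abs(np.linalg.norm(n_hat) - 1.0) > 1e-8:
        raise ValueError("n_hat must be a unit vector")
    y2 = np.array([real_sph_harm(2, m, n_hat) for m in range(-2, 3)])
    num = np.tensordot(y2, field.coeffs[_L2], axes=(0, 0))
    with np.errstate(divide="ignore", invalid="ignore"):
        op = (2.0 * np.sqrt(np.pi) / 5.0) * num / field.coeffs[0]
    op[field.coeffs[0] <= 0] = np.nan
    return op


def op_distance_profile(
    field: SHField,
    structure_mask: np.ndarray,
    n_hat: np.ndarray,
    max_distance_vox: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean OP as a function of Euclidean distance (nm) to a structure.

    Distances come from the exact distance transform of the mask, binned at
    one voxel; the OP of all voxels falling in a bin is averaged (NaN-aware).
    Returns (bin_centers_nm, mean_op).
    """
    structure_mask = np.asarray(structure_mask, dtype=bool)
    if not structure_mask.any():
        raise ValueError("structure mask is empty")
    dist = distance_transform_edt(~structure_mask)
    op = op_map(field, n_hat)
    bins = np.round(dist).astype(int)
    nmax = int(bins.max()) if max_distance_vox is None else max_distance_vox
    centers, means = [], []
    for b in range(nmax + 1):
        vals = op[bins == b]
        vals = vals[np.isfinite(vals)]
        if vals.size:
            centers.append(b * field.voxel_size)
            means.append(float(vals.mean()))
    return np.array(centers), np.array(means)
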