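"""Synthetic spatio-angular phantoms: shell, spheres, helices, double helix, GUV.

Each phantom is an SHField whose voxels carry an axially symmetric
Watson-style ODF kernel exp(kappa (mu.s)^2) projected onto the even l <= 4
band, pointed along a geometry-defined direction (radial for shells/spheres/
GUVs, tangential for helices).  The kernel concentration kappa is mapped from
a requested generalized fractional anisotropy (GFA) through a precomputed
monotone lookup, so anisotropy ramps are specified directly in GFA units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.ndimage import gaussian_filter

from .field import SHField
from .sphere import EVEN_CHANNELS, N_CHANNELS, real_sph_harm


class GeometryError(ValueError):
    """Raised when a phantom does not fit its grid."""


# ----------------------------------------------------------- Watson kernels
_DEGREES = (0, 2, 4)


def watson_zonal_coeffs(kappa: float) -> np.ndarray:
    """Zonal coefficients z_l = int exp(kappa t^2) Y_l0 for l = 0, 2, 4.

    Normalized so the kernel integrates to 1 on the sphere (z_0 = Y_00).
    """
    t, w = leggauss(48)
    f = np.exp(kappa * (t**2 - 1.0))  # -1 shift for numeric range only
    norm = 2.0 * np.pi * np.sum(w * f)
    zs = []
    for l in _DEGREES:
        dirs = np.column_stack([np.sqrt(1 - t**2), np.zeros_like(t), t])
        y = real_sph_harm(l, 0, dirs)
        zs.append(2.0 * np.pi * np.sum(w * f * y) / norm)
    return np.array(zs)


def kernel_gfa(kappa: float) -> float:
    """GFA of the band-limited Watson kernel (independent of its orientation)."""
    z = watson_zonal_coeffs(kappa)
    return float(np.sqrt(1.0 - z[0] ** 2 / np.sum(z**2)))


_KAPPA_GRID = np.concatenate([[0.0], np.geomspace(0.05, 80.0, 120)])
_GFA_TABLE: np.ndarray | None = None


def kappa_for_gfa(gfa: np.ndarray | float) -> np.ndarray:
    """Invert the kappa -> GFA map (monotone) via the precomputed lookup."""
    global _GFA_TABLE
    if _GFA_TABLE is None:
        _GFA_TABLE = np.array([kernel_gfa(k) for k in _KAPPA_GRID])
    g = np.clip(np.asarray(gfa, dtype=float), 0.0, _GFA_TABLE[-1] - 1e-6)
    return np.interp(g, _GFA_TABLE, _KAPPA_GRID)


def oriented_kernel(mu: np.ndarray, kappa: np.ndarray) -> np.ndarray:
    """Watson kernel coefficients pointed along per-voxel axes mu.

    ``mu``: (n, 3) unit axes; ``kappa``: (n,) concentrations.  Returns
    (15, n) with F_00 = 1 for every voxel (unit density), using the zonal
    rotation identity F_lm(mu) = z_l sqrt(4 pi / (2l+1)) Y_lm(mu).
    """
    mu = np.asarray(mu, dtype=float)
    kappa = np.atleast_1d(np.asarray(kappa, dtype=float))
    uniq, inv = np.unique(np.round(kappa, 6), return_inverse=True)
    zs = np.stack([watson_zonal_coeffs(k) for k in uniq])[inv]  # (n, 3)
    out = np.zeros((N_CHANNELS, mu.shape[0]))
    for i, (l, m) in enumerate(EVEN_CHANNELS):
        li = _DEGREES.index(l)
        out[i] = zs[:, li] * np.sqrt(4.0 * np.pi / (2 * l + 1)) * real_sph_harm(l, m, mu)
    out /= out[0]  # unit density channel
    return out


# ----------------------------------------------------------------- assembly
def _grid_coords(shape: tuple[int, int, int]) -> tuple[np.ndarray, ...]:
    nz, ny, nx = shape
    z = np.arange(nz)[:, None, None] - nz // 2
    y = np.arange(ny)[None, :, None] - ny // 2
    x = np.arange(nx)[None, None, :] - nx // 2
    return np.broadcast_arrays(z, y, x)


def _assemble(
    density: np.ndarray,
    axes: np.ndarray,
    gfa: np.ndarray,
    voxel_size: float,
    support_rel: float = 1e-4,
) -> SHField:
    """Attach oriented kernels to a density volume.

    ``axes`` is (3, nz, ny, nx) (may be unnormalized; zero where undefined),
    ``gfa`` a volume of requested anisotropy.
    """
    coeffs = np.zeros((N_CHANNELS,) + density.shape)
    coeffs[0] = density
    support = density > support_rel * density.max()
    norms = np.linalg.norm(axes, axis=0)
    ok = support & (norms > 1e-12)
    mu = (axes[:, ok] / norms[ok]).T
    kap = kappa_for_gfa(gfa[ok])
    k = oriented_kernel(mu, kap)  # (15, n), unit density
    coeffs[:, ok] = k * density[ok]
    return SHField(coeffs, voxel_size)


@dataclass(frozen=True)
class PhantomSpec:
    """Common knobs shared by the generators (documented per function)."""

    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size: float = 130.0
    gfa: float = 0.6
    seed: int = 0


# ------------------------------------------------------------------- shell
def make_shell(
    shape: tuple[int, int, int] = (64, 64, 64),
    radius: float = 30.0,
    sigma: float = 2.0,
    density: float = 600.0,
    gfa: float = 0.6,
    voxel_size: float = 130.0,
) -> SHField:
    """Spherical shell: 1-voxel thickness, Gaussian-smoothed boundary,
    uniform density, radial dipole axes, constant GFA."""
    if radius + 1 > min(shape) / 2:
        raise GeometryError("shell radius exceeds the grid")
    z, y, x = _grid_coords(shape)
    r = np.sqrt(z**2 + y**2 + x**2).astype(float)
    rho = np.where(np.abs(r - radius) < 0.5, density, 0.0)
    rho = gaussian_filter(rho, sigma)
    axes = np.stack([x, y, z]).astype(float)  # radial, (x, y, z) components
    return _assemble(rho, axes, np.full(shape, gfa), voxel_size)


# ------------------------------------------------------------------ spheres
def make_spheres(
    shape: tuple[int, int, int] = (128, 128, 128),
    n_spheres: int = 12,
    density_range: tuple[float, float] = (500.0, 900.0),
    radius_range: tuple[float, float] = (2.0, 6.0),
    gfa: float = 0.6,
    voxel_size: float = 130.0,
    seed: int = 0,
) -> SHField:
    """Random solid spheres with Gaussian-decaying density and radial axes.

    Central densities are uniform in ``density_range`` (counts), radii uniform
    in ``radius_range`` (voxels).  Where spheres overlap, densities add and
    the axis of the locally dominant sphere wins.  Bit-reproducible per seed.
    """
    rng = np.random.default_rng(seed)
    z, y, x = (c.astype(float) for c in _grid_coords(shape))
    rho = np.zeros(shape)
    best = np.zeros(shape)
    axes = np.zeros((3,) + shape)
    margin = radius_range[1] + 1
    for _ in range(n_spheres):
        c = rng.uniform(margin, np.array(shape) - margin) - np.array(shape) // 2
        amp = rng.uniform(*density_range)
        rad = rng.uniform(*radius_range)
        dz, dy, dx = z - c[0], y - c[1], x - c[2]
        d = np.sqrt(dz**2 + dy**2 + dx**2)
        contrib = np.where(d <= rad, amp * np.exp(-0.5 * (d / (rad / 2.0)) ** 2), 0.0)
        rho += contrib
        take = contrib > best
        for i, comp in enumerate((dx, dy, dz)):
            axes[i][take] = comp[take]
        best = np.maximum(best, contrib)
    return _assemble(rho, axes, np.full(shape, gfa), voxel_size)


# ------------------------------------------------------------------ helices
def _paint_curve(
    shape: tuple[int, int, int],
    points: np.ndarray,
    tangents: np.ndarray,
    attrs: np.ndarray,
    tube_radius: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rasterize a curve: density 1 within tube_radius (voxels) of the
    centerline; each voxel inherits the tangent/attribute of its nearest
    centerline sample."""
    dist = np.full(shape, np.inf)
    axes = np.zeros((3,) + shape)
    attr = np.zeros(shape)
    r = int(np.ceil(tube_radius)) + 1
    nz, ny, nx = shape
    for p, t, a in zip(points, tangents, attrs):
        iz, iy, ix = (int(round(c)) for c in p)
        sl = (
            slice(max(iz - r, 0), min(iz + r + 1, nz)),
            slice(max(iy - r, 0), min(iy + r + 1, ny)),
            slice(max(ix - r, 0), min(ix + r + 1, nx)),
        )
        zz, yy, xx = np.mgrid[sl]
        d = np.sqrt((zz - p[0]) ** 2 + (yy - p[1]) ** 2 + (xx - p[2]) ** 2)
        closer = d < dist[sl]
        dist[sl][closer] = d[closer]
        attr[sl][closer] = a
        for i in range(3):
            axes[i][sl][closer] = t[i]  # components stored (x, y, z) by caller
    density = (dist <= tube_radius).astype(float)
    return density, axes, attr


def helix_centerline(
    helix_radius_vox: float,
    pitch_vox: float,
    length_vox: float,
    phase: float = 0.0,
    samples_per_voxel: float = 4.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Centerline points and unit tangents of a z-axis helix, in voxel units.

    Points are (z, y, x) offsets around the axis origin; the tangent at angle
    theta is proportional to (-R sin theta, R cos theta, pitch / 2 pi) in
    (x, y, z) components.
    """
    n = max(int(length_vox * samples_per_voxel), 8)
    zs = np.linspace(-length_vox / 2, length_vox / 2, n)
    theta = 2.0 * np.pi * zs / pitch_vox + phase
    pts = np.column_stack(
        [zs, helix_radius_vox * np.sin(theta), helix_radius_vox * np.cos(theta)]
    )  # (z, y, x)
    tan = np.column_stack(
        [
            -helix_radius_vox * np.sin(theta) * 2 * np.pi / pitch_vox,  # x
            helix_radius_vox * np.cos(theta) * 2 * np.pi / pitch_vox,  # y
            np.ones_like(theta),  # z
        ]
    )
    tan /= np.linalg.norm(tan, axis=1, keepdims=True)
    return pts, tan


def make_helices(
    shape: tuple[int, int, int] = (64, 64, 64),
    helix_radius: float = 600.0,
    pitch: float = 1000.0,
    tube_radius_vox: float = 1.4,
    density: float = 600.0,
    gfa_range: tuple[float, float] = (0.3, 0.8),
    voxel_size: float = 130.0,
) -> SHField:
    """Three single helices aligned with the x, y and z axes.

    Each helix has 600 nm radius and 1000 nm pitch by default, uniform tube
    density, tangential dipole axes, and a monotone GFA ramp along arc length
    (``gfa_range``).  The three are placed equidistant along x, each within a
    20x20x20-voxel bounding box.
    """
    rv = helix_radius / voxel_size
    pv = pitch / voxel_size
    box = 20.0
    if 2 * (rv + tube_radius_vox) > box or shape[0] < box:
        raise GeometryError("helix radius inconsistent with its bounding box")
    pts_z, tan_z = helix_centerline(rv, pv, box - 2 * tube_radius_vox)
    n = len(pts_z)
    gfa_line = np.linspace(*gfa_range, n)
    density_total = np.zeros(shape)
    axes = np.zeros((3,) + shape)
    gfa_vol = np.zeros(shape)
    centers = np.linspace(0, shape[2], 5)[1:4] - shape[2] // 2
    for axis, cx in zip(("z", "y", "x"), centers):
        if axis == "z":
            pts, tan = pts_z, tan_z
        elif axis == "y":  # rotate helix axis z -> y: (z,y,x) -> (y,z,x)
            pts = pts_z[:, [1, 0, 2]]
            tan = tan_z[:, [0, 2, 1]]  # swap y, z components of (x, y, z)
        else:  # z -> x
            pts = pts_z[:, [2, 1, 0]]
            tan = tan_z[:, [2, 1, 0]]  # swap x, z components
        shift = np.array([0.0, 0.0, cx]) + np.array(shape) // 2
        d, a, g = _paint_curve(shape, pts + shift, tan, gfa_line, tube_radius_vox)
        density_total += density * d
        mask = d > 0
        for i in range(3):
            axes[i][mask] = a[i][mask]
        gfa_vol[mask] = g[mask]
    return _assemble(density_total, axes, gfa_vol, voxel_size)


def make_double_helix(
    shape: tuple[int, int, int] = (128, 128, 128),
    helix_radius: float = 600.0,
    pitch: float = 7020.0,
    inner_space: float = 554.0,
    tube_radius_vox: float = 1.4,
    density: float = 600.0,
    gfa_range: tuple[float, float] = (0.25, 0.8),
    voxel_size: float = 130.0,
) -> SHField:
    """Two intertwined helices around a common z axis, DNA-style.

    Both strands wind at ``helix_radius`` with the double-helix ``pitch``;
    their azimuthal offset is set so the strand separation at equal height is
    ``inner_space`` (chord 2 R sin(dphi/2)).  Dipole axes are tangential and
    the GFA ramps from bottom to top.  Defaults follow the 554 nm / 7020 nm
    phantom; the companion uses 478 nm / 7280 nm.
    """
    if inner_space < voxel_size:
        raise GeometryError("inner spacing below the voxel size")
    if inner_space > 2 * helix_radius:
        raise GeometryError("inner spacing exceeds the strand-circle diameter")
    rv = helix_radius / voxel_size
    pv = pitch / voxel_size
    dphi = 2.0 * np.arcsin(inner_space / (2.0 * helix_radius))
    length = min(shape[0] - 4 * tube_radius_vox, shape[0] - 2)
    density_total = np.zeros(shape)
    axes = np.zeros((3,) + shape)
    gfa_vol = np.zeros(shape)
    center = np.array(shape) // 2
    for phase in (0.0, dphi):
        pts, tan = helix_centerline(rv, pv, length, phase=phase)
        gfa_line = np.interp(
            pts[:, 0], [pts[0, 0], pts[-1, 0]], gfa_range
        )  # ramp along z (bottom -> top)
        d, a, g = _paint_curve(shape, pts + center, tan, gfa_line, tube_radius_vox)
        new = d > 0
        density_total = np.maximum(density_total, density * d)
        for i in range(3):
            axes[i][new] = a[i][new]
        gfa_vol[new] = g[new]
    return _assemble(density_total, axes, gfa_vol, voxel_size)


def double_helix_centerlines(
    helix_radius: float = 600.0,
    pitch: float = 7020.0,
    inner_space: float = 554.0,
    length_vox: float = 120.0,
    voxel_size: float = 130.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Centerline samples (voxel units, (z,y,x)) of the two strands."""
    rv, pv = helix_radius / voxel_size, pitch / voxel_size
    dphi = 2.0 * np.arcsin(inner_space / (2.0 * helix_radius))
    a, _ = helix_centerline(rv, pv, length_vox, 0.0)
    b, _ = helix_centerline(rv, pv, length_vox, dphi)
    return a, b


# --------------------------------------------------------------------- GUV
def make_guv(
    shape: tuple[int, int, int] = (128, 128, 128),
    diameter_um: float = 10.0,
    sigma: float = 1.0,
    density: float = 600.0,
    gfa: float = 0.6,
    voxel_size: float = 130.0,
) -> SHField:
    """Giant-unilamellar-vesicle phantom: a 1-voxel membrane with dipoles
    normal to the surface.  Pair presets: 10 um and 5 um diameter."""
    radius = diameter_um * 1000.0 / (2.0 * voxel_size)
    return make_shell(shape, radius, sigma, density, gfa, voxel_size)
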