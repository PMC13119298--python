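"""Similarity metrics for spatio-angular reconstructions.

Four scalar comparisons: SSIM on density maps, OSIM (mean-squared ODF-shape
difference), ONCC (voxel-wise normalized cross-correlation of ODF shapes),
and PSIM (mean absolute dot product of peak-orientation axes).  Orientation
metrics run on a ground-truth support mask (1% of peak density by default) so
empty background does not dominate them; SSIM follows the convention of being
computed on the whole density map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity

from .field import SHField
from .sphere import SphereGrid, sh_synthesize


def support_mask(density: np.ndarray, frac: float = 0.01) -> np.ndarray:
    """Voxels with density above ``frac`` of the maximum."""
    return density > frac * density.max()


def ssim(
    density_a: np.ndarray, density_b: np.ndarray, windowed: bool = True
) -> float:
    """Structural similarity of two density volumes.

    ``windowed=True`` (default) is the standard local-window SSIM with
    k1 = 0.01, k2 = 0.03 and the data range taken from the reference (first
    argument); ``windowed=False`` evaluates the global single-window form.
    """
    a = np.asarray(density_a, dtype=float)
    b = np.asarray(density_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("density volumes must share a shape")
    rng = a.max() - a.min()
    if windowed:
        return float(structural_similarity(a, b, data_range=rng))
    c1, c2 = (0.01 * rng) ** 2, (0.03 * rng) ** 2
    mu_a, mu_b = a.mean(), b.mean()
    va, vb = a.var(), b.var()
    cov = np.mean((a - mu_a) * (b - mu_b))
    return float(
        (2 * mu_a * mu_b + c1)
        * (2 * cov + c2)
        / ((mu_a**2 + mu_b**2 + c1) * (va + vb + c2))
    )


def _samples(field: SHField, grid: SphereGrid, mask: np.ndarray) -> np.ndarray:
    return sh_synthesize(field.coeffs[:, mask], grid)  # (O, n)


def osim(
    field_a: SHField,
    field_b: SHField,
    grid: SphereGrid,
    mask: np.ndarray | None = None,
) -> float:
    """1 - mean over voxels of the mean squared ODF-sample difference."""
    if field_a.shape != field_b.shape:
        raise ValueError("fields must share a grid")
    if mask is None:
        mask = support_mask(field_a.density)
    fa = _samples(field_a, grid, mask)
    fb = _samples(field_b, grid, mask)
    return float(1.0 - np.mean(np.mean((fa - fb) ** 2, axis=0)))


class DegenerateMetricError(ValueError):
    """Raised when every voxel is angularly constant and ONCC is undefined."""


def oncc(
    field_a: SHField,
    field_b: SHField,
    grid: SphereGrid,
    mask: np.ndarray | None = None,
) -> float:
    """Mean voxel-wise normalized cross-correlation of ODF shapes, in [-1, 1].

    Voxels whose sampled ODF has zero variance in either field are skipped
    (and counted out of the average).
    """
    if field_a.shape != field_b.shape:
        raise ValueError("fields must share a grid")
    if mask is None:
        mask = support_mask(field_a.density)
    fa = _samples(field_a, grid, mask)
    fb = _samples(field_b, grid, mask)
    # degenerate = angularly constant relative to its own magnitude
    floor_a = 1e-20 * np.mean(fa**2, axis=0) * grid.count
    floor_b = 1e-20 * np.mean(fb**2, axis=0) * grid.count
    fa = fa - fa.mean(axis=0)
    fb = fb - fb.mean(axis=0)
    pa = np.sum(fa**2, axis=0)
    pb = np.sum(fb**2, axis=0)
    ok = (pa > floor_a) & (pb > floor_b)
    if not np.any(ok):
        raise DegenerateMetricError("all voxels have angularly constant ODFs")
    vals = np.sum(fa[:, ok] * fb[:, ok], axis=0) / np.sqrt(pa[ok] * pb[ok])
    return float(np.mean(vals))


def psim(
    peaks_a: np.ndarray,
    peaks_b: np.ndarray,
    mask: np.ndarray,
    signed: bool = False,
) -> float:
    """Mean (absolute) dot product of peak-orientation axes over a mask.

    Dipole orientations are axes, so the default takes |dot|; the signed
    variant is exposed for completeness.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    d = np.sum(peaks_a[mask] * peaks_b[mask], axis=-1)
    return float(np.mean(d if signed else np.abs(d)))


@dataclass
class MetricReport:
    """The four comparisons plus the context they were computed in."""

    ssim: float
    osim: float
    oncc: float
    psim: float
    n_support: int
    sphere_points: int

    def as_dict(self) -> dict:
        return {
            "ssim": self.ssim,
            "osim": self.osim,
            "oncc": self.oncc,
            "psim": self.psim,
            "n_support": self.n_support,
            "sphere_points": self.sphere_points,
        }


def compare_fields(
    truth: SHField,
    estimate: SHField,
    grid: SphereGrid | None = None,
    mask: np.ndarray | None = None,
) -> MetricReport:
    """Full report of an estimate against ground truth."""
    from .odf_maps import peak_orientation

    grid = grid or SphereGrid.fibonacci(1000)
    if mask is None:
        mask = support_mask(truth.density)
    pa = peak_orientation(truth, grid, mask=mask)
    pb = peak_orientation(estimate, grid, mask=mask)
    return MetricReport(
        ssim=ssim(truth.density, estimate.density),
        osim=osim(truth, estimate, grid, mask),
        oncc=oncc(truth, estimate, grid, mask),
        psim=psim(pa, pb, mask),
        n_support=int(mask.sum()),
        sphere_points=grid.count,
    )
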