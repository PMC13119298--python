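import numpy as np
import pytest

from polodf.field import SHField
from polodf.odf_maps import (
    canonicalize_axes,
    density_map,
    gfa_map,
    op_distance_profile,
    op_map,
    peak_orientation,
    principal_orientation,
)
from polodf.phantoms import make_shell, oriented_kernel
from polodf.sphere import SphereGrid, real_sph_harm
from polodf.wigner import rotate_field_y90, wigner_y90

Z = np.array([0.0, 0.0, 1.0])
Y = np.array([0.0, 1.0, 0.0])


def field_from_voxels(coeff_list, voxel_size=130.0):
    c = np.zeros((15, len(coeff_list), 1, 1))
    for i, v in enumerate(coeff_list):
        c[:, i, 0, 0] = v
    return SHField(c, voxel_size)


@pytest.fixture(scope="module")
def grid():
    return SphereGrid.fibonacci(2562)


class TestDensity:
    def test_density_is_isotropic_channel(self):
        iso = np.zeros(15)
        iso[0] = 7.5
        fld = field_from_voxels([iso])
        assert density_map(fld)[0, 0, 0] == 7.5

    def test_density_invariant_under_view_rotation(self):
        shell = make_shell((16, 16, 16), radius=5.0, sigma=1.0)
        rot = rotate_field_y90(shell.coeffs, wigner_y90())
        assert np.abs(np.sort(rot[0].ravel()) - np.sort(shell.density.ravel())).max() < 1e-10


class TestPeakOrientation:
    def test_axial_kernel_peaks_at_its_axis(self, grid):
        k = oriented_kernel(Z[None], np.array([6.0]))[:, 0]
        fld = field_from_voxels([k])
        peak = peak_orientation(fld, grid)[0, 0, 0]
        assert abs(peak @ Z) > 0.9999

    def test_zero_field_gives_zero_vectors(self, grid):
        fld = field_from_voxels([np.zeros(15)])
        assert np.all(peak_orientation(fld, grid) == 0.0)

    def test_canonical_hemisphere(self, grid):
        k = oriented_kernel(-Z[None], np.array([6.0]))[:, 0]
        fld = field_from_voxels([k])
        peak = peak_orientation(fld, grid)[0, 0, 0]
        assert peak[2] >= 0.0  # z >= 0 hemisphere

    def test_canonicalize_tie_break(self):
        v = canonicalize_axes(np.array([[0.0, -1.0, 0.0], [-1.0, 0.0, 0.0]]))
        assert v[0, 1] == 1.0 and v[1, 0] == 1.0


class TestPrincipalOrientation:
    def test_single_lobe_matches_peak(self, grid):
        k = oriented_kernel(Y[None], np.array([8.0]))[:, 0]
        fld = field_from_voxels([k])
        pk = peak_orientation(fld, grid)[0, 0, 0]
        pr = principal_orientation(fld, grid)[0, 0, 0]
        assert abs(pk @ pr) > 0.995

    def test_symmetric_two_lobe_bisector(self, grid):
        """Two equal lobes at +-30 degrees from z in the xz-plane: the
        maximum-projection direction is the bisector z.  (+-45 degrees would
        be degenerate: for axial lobes 90 degrees apart, x is a bisector too.)"""
        a = np.array([np.sin(np.pi / 6), 0.0, np.cos(np.pi / 6)])
        b = np.array([-np.sin(np.pi / 6), 0.0, np.cos(np.pi / 6)])
        k = oriented_kernel(np.stack([a, b]), np.array([8.0, 8.0])).sum(axis=1)
        fld = field_from_voxels([k])
        pr = principal_orientation(fld, grid)[0, 0, 0]
        assert abs(pr @ Z) > 0.99

    def test_matches_brute_force(self, grid):
        rng = np.random.default_rng(0)
        c = rng.normal(size=15)
        c[0] = abs(c[0]) + 3
        fld = field_from_voxels([c])
        pr = principal_orientation(fld, grid)[0, 0, 0]
        from polodf.sphere import sh_synthesize

        f = sh_synthesize(c, grid)
        scores = np.abs(grid.directions @ grid.directions.T) @ (grid.weights * f)
        best = canonicalize_axes(grid.directions[np.argmax(scores)])
        assert abs(pr @ best) > 0.9999


class TestGFA:
    def test_isotropic_zero(self):
        iso = np.zeros(15)
        iso[0] = 3.0
        assert gfa_map(field_from_voxels([iso]))[0, 0, 0] == 0.0

    def test_bounded_below_one(self):
        rng = np.random.default_rng(1)
        c = rng.normal(size=(15, 30))
        fld = field_from_voxels(list(c.T))
        g = gfa_map(fld)
        assert np.all((g >= 0) & (g < 1))

    def test_monotone_in_concentration(self):
        kappas = np.array([0.5, 2.0, 8.0, 32.0])
        ks = oriented_kernel(np.tile(Z, (4, 1)), kappas)
        fld = field_from_voxels(list(ks.T))
        g = gfa_map(fld)[:, 0, 0]
        assert np.all(np.diff(g) > 0)


class TestOrderParameter:
    def test_isotropic_zero(self):
        iso = np.zeros(15)
        iso[0] = 2.0
        assert op_map(field_from_voxels([iso]), Z)[0, 0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_delta_along_axis_is_unity(self):
        """A perfectly aligned ODF (exact delta coefficients) reaches OP = 1:
        the l=2 content of delta(s - n) gives <P2> = 1."""
        from polodf.sphere import EVEN_CHANNELS

        c = np.array([real_sph_harm(l, m, Z) for l, m in EVEN_CHANNELS])
        assert op_map(field_from_voxels([c]), Z)[0, 0, 0] == pytest.approx(1.0, abs=1e-10)

    def test_perpendicular_plane_is_minus_half(self):
        from polodf.sphere import EVEN_CHANNELS

        c = np.array([real_sph_harm(l, m, np.array([1.0, 0, 0])) for l, m in EVEN_CHANNELS])
        assert op_map(field_from_voxels([c]), Z)[0, 0, 0] == pytest.approx(-0.5, abs=1e-10)

    def test_triad_sums_to_zero(self):
        rng = np.random.default_rng(2)
        c = rng.normal(size=15)
        c[0] = abs(c[0]) + 2
        fld = field_from_voxels([c])
        total = sum(
            op_map(fld, n)[0, 0, 0]
            for n in (Z, Y, np.array([1.0, 0.0, 0.0]))
        )
        assert total == pytest.approx(0.0, abs=1e-10)

    def test_quadrature_oracle(self, grid):
        """OP equals the quadrature average of P2(s.n) under the ODF."""
        from polodf.sphere import sh_synthesize

        rng = np.random.default_rng(3)
        c = np.zeros(15)
        c[:6] = rng.normal(size=6)
        c[0] = abs(c[0]) + 2
        fld = field_from_voxels([c])
        f = sh_synthesize(c, grid)
        cos = grid.directions @ Z
        p2 = 0.5 * (3 * cos**2 - 1)
        expect = np.sum(grid.weights * f * p2) / np.sum(grid.weights * f)
        assert op_map(fld, Z)[0, 0, 0] == pytest.approx(expect, abs=1e-3)

    def test_nonunit_axis_rejected(self):
        with pytest.raises(ValueError):
            op_map(field_from_voxels([np.ones(15)]), np.array([0.0, 0.0, 2.0]))

    def test_nan_outside_support(self):
        fld = field_from_voxels([np.zeros(15)])
        assert np.isnan(op_map(fld, Z)[0, 0, 0])


class TestOPDistanceProfile:
    def _field_with_planted_profile(self, n=24, lam_vox=4.0):
        """OP decays as exp(-d / lam) away from a central rod along y."""
        from scipy.ndimage import distance_transform_edt

        mask = np.zeros((n, n, n), dtype=bool)
        mask[n // 2, :, n // 2] = True
        d = distance_transform_edt(~mask)
        target_op = np.exp(-d / lam_vox)
        # mix an aligned kernel with an isotropic one to hit the target OP
        kz = oriented_kernel(Y[None], np.array([200.0]))[:, 0]
        op_max = (2 * np.sqrt(np.pi) / 5) * np.sum(
            kz[1:6] * [real_sph_harm(2, m, Y) for m in range(-2, 3)]
        ) / kz[0]
        w = np.clip(target_op / op_max, 0.0, 1.0)
        c = np.zeros((15, n, n, n))
        c[0] = 1.0
        for ch in range(1, 6):
            c[ch] = w * kz[ch]
        return SHField(c), mask, float(op_max), d

    def test_planted_profile_recovered(self):
        fld, mask, op_max, d = self._field_with_planted_profile()
        dist, mean_op = op_distance_profile(fld, mask, Y)
        planted = np.exp(-dist / (4.0 * 130.0)) * op_max  # value at bin centers
        keep = slice(0, 6)
        assert np.abs(planted[keep] - np.array(mean_op)[keep]).max() / op_max < 0.12

    def test_flat_field_flat_profile(self):
        n = 16
        mask = np.zeros((n, n, n), dtype=bool)
        mask[8, 8, 8] = True
        k = oriented_kernel(Z[None], np.array([5.0]))[:, 0]
        c = np.tile(k[:, None, None, None], (1, n, n, n))
        dist, mean_op = op_distance_profile(SHField(c), mask, Z)
        assert np.ptp(mean_op) < 1e-10

    def test_zero_distance_bin_is_mask(self):
        n = 12
        mask = np.zeros((n, n, n), dtype=bool)
        mask[6, 6, 6] = True
        k = oriented_kernel(Z[None], np.array([5.0]))[:, 0]
        c = np.tile(k[:, None, None, None], (1, n, n, n))
        dist, _ = op_distance_profile(SHField(c), mask, Z)
        assert dist[0] == 0.0

    def test_empty_mask_rejected(self):
        fld = field_from_voxels([np.ones(15)])
        with pytest.raises(ValueError):
            op_distance_profile(fld, np.zeros(fld.shape, dtype=bool), Z)


class TestRotationEquivariance:
    def test_peaks_follow_view_rotation(self, grid):
        shell = make_shell((16, 16, 16), radius=5.0, sigma=1.0)
        W = wigner_y90()
        rot = SHField(rotate_field_y90(shell.coeffs, W), shell.voxel_size)
        mask = shell.density > 0.3 * shell.density.max()
        peaks = peak_orientation(shell, grid, mask=mask)
        mask_r = np.swapaxes(mask, 0, 2)
        peaks_r = peak_orientation(rot, grid, mask=mask_r)
        # the direction map x<->z applied to the original peaks
        mapped = canonicalize_axes(np.swapaxes(peaks, 0, 2)[..., [2, 1, 0]])
        dots = np.abs(np.sum(mapped[mask_r] * peaks_r[mask_r], axis=-1))
        assert np.median(dots) > 0.999
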