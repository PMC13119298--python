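import numpy as np
import pytest

from polodf.field import SHField
from polodf.gaunt import gaunt_tensor
from polodf.psf import (
    AcquisitionScheme,
    OpticalConfig,
    PolarizationState,
    detection_psf,
    excitation_coeffs,
    make_back_projector,
    preset_scheme,
    pupil_g,
    system_psf,
)
from polodf.simulate import MeasurementSet, back_project, forward_project
from polodf.sphere import SphereGrid, real_sph_harm, sh_synthesize
from polodf.wigner import wigner_y90

Z = np.array([0.0, 0.0, 1.0])
X = np.array([1.0, 0.0, 0.0])


class TestExcitation:
    def test_isotropic_channel_constant(self):
        for p in (Z, X, np.array([0.6, 0.8, 0.0])):
            assert excitation_coeffs(p)[0] == pytest.approx(2 * np.sqrt(np.pi), abs=1e-12)

    def test_l4_channels_vanish(self):
        assert np.abs(excitation_coeffs(Z)[6:]).max() == 0.0

    def test_pole_values(self):
        P = excitation_coeffs(Z)
        assert P[3] == pytest.approx((8 * np.pi / 5) * np.sqrt(5 / (4 * np.pi)), abs=1e-10)
        assert np.abs(P[[1, 2, 4, 5]]).max() < 1e-12

    def test_nonunit_rejected(self):
        with pytest.raises(ValueError):
            excitation_coeffs(np.array([0.0, 0.0, 2.0]))

    def test_pattern_is_three_cos_squared(self, fib_grid):
        # synthesizing P_lm reproduces 3|p.s|^2 exactly (band-limited identity)
        p = np.array([0.0, 0.6, 0.8])
        vals = sh_synthesize(excitation_coeffs(p), fib_grid)
        expect = 3.0 * (fib_grid.directions @ p) ** 2
        assert np.abs(vals - expect).max() < 1e-10


class TestPupil:
    def test_g02_is_radial_cosine(self):
        rho = np.array([0.3, 0.5])
        g = pupil_g(rho, np.zeros(2))
        assert np.allclose(g[0, 2], rho)  # g02(tau) = |tau| cos(phi) at phi=0
        assert np.allclose(g[1, 2], 0.0)

    def test_defocus_mirror_symmetry(self):
        # aberration-free defocus: the irradiance at +d is the spatial mirror
        # of the irradiance at -d
        from polodf.psf import pupil_fields

        cfg = OpticalConfig()
        n = 16
        bp = pupil_fields(cfg, +260.0, (n, n))
        bm = pupil_fields(cfg, -260.0, (n, n))
        Bp = np.einsum("ij...,ik...->jk...", bp, bp.conj()).real
        Bm = np.einsum("ij...,ik...->jk...", bm, bm.conj()).real
        grid = (2 * (n // 2) - np.arange(n)) % n
        mirrored = Bm[:, :, grid][:, :, :, grid]
        # edge row/col of the crop wraps outside the field of view; compare interior
        inner = (slice(None), slice(None), slice(1, n), slice(1, n))
        assert np.abs(Bp[inner] - mirrored[inner]).max() < 1e-8 * np.abs(Bp).max()


class TestDetection:
    @pytest.fixture(scope="class")
    def det(self, config):
        return detection_psf(config, (17, 17, 17))

    def test_l4_channels_zero(self, det):
        assert np.abs(det[6:]).max() == 0.0

    def test_nonnegative_over_orientations(self, det, fib_grid):
        vals = sh_synthesize(det, fib_grid)
        assert vals.min() > -1e-9 * vals.max()

    def test_axial_dipole_darker_than_lateral(self, det):
        center = det[:, 8, 8, 8]
        pair = SphereGrid(
            np.array([Z, X]), np.array([2 * np.pi, 2 * np.pi])
        )
        resp_z, resp_x = sh_synthesize(center, pair)
        assert resp_z < resp_x

    def test_irradiance_matrix_positive_semidefinite(self, config):
        from polodf.psf import pupil_fields

        beta = pupil_fields(config, 390.0, (12, 12))
        B = np.einsum("ij...,ik...->jk...", beta, beta.conj())
        B = np.moveaxis(B, (0, 1), (-2, -1))
        eig = np.linalg.eigvalsh(B)
        assert eig.min() > -1e-10 * eig.max()


class TestSystemResponse:
    def test_unknown_modality(self, config):
        with pytest.raises(ValueError):
            system_psf(config, preset_scheme("scheme6"), (8, 8, 8), modality="confocal")

    def test_odd_and_high_band_empty(self, config):
        resp = system_psf(
            config, preset_scheme("scheme6").for_view("A"), (12, 12, 12),
            modality="spim", pad=0,
        )
        # all channels live in the even l <= 4 band by construction (15
        # channels); the response to l=4 is generated only by the
        # excitation x detection product
        assert resp.psf.shape[1] == 15

    def test_spim_midplane_unattenuated(self, config):
        """On the sheet mid-plane the Gaussian factor is 1, so the SPIM PSF
        equals the same-geometry response without optical sectioning (an
        effectively infinite sheet waist)."""
        shape = (13, 13, 13)
        scheme = AcquisitionScheme((PolarizationState("A", 30.0, 0.0),))
        sp = system_psf(config, scheme, shape, modality="spim", pad=0)
        wide = OpticalConfig(sheet_waist=1e12)
        un = system_psf(wide, scheme, shape, modality="spim", pad=0)
        mid = shape[0] // 2
        assert np.abs(un.psf[0, :, mid] - sp.psf[0, :, mid]).max() < 1e-10
        # and off the mid-plane the sheet attenuates
        assert sp.psf[0, 0, 2].sum() < un.psf[0, 0, 2].sum()

    def test_sheet_energy_monotone_in_waist(self, config):
        shape = (13, 13, 13)
        scheme = AcquisitionScheme((PolarizationState("A", 30.0, 0.0),))
        energies = []
        for w0 in (600.0, 1200.0, 2400.0):
            cfg = OpticalConfig(sheet_waist=w0)
            resp = system_psf(cfg, scheme, shape, modality="spim", pad=0)
            energies.append(resp.psf[0, 0].sum())
        assert energies[0] < energies[1] < energies[2]

    def test_view_b_equals_rotated_view_a(self, config):
        """View-B response = view-A volume transposed x<->z with SH channels
        mixed by the dual-view Wigner blocks (same NA for the check)."""
        shape = (12, 12, 12)
        cfg = OpticalConfig(na_b=config.na)  # equal NA isolates the rotation
        a = system_psf(
            cfg, AcquisitionScheme((PolarizationState("A", 40.0, 0.0),)),
            shape, modality="dispim", pad=0,
        )
        b = system_psf(
            cfg, AcquisitionScheme((PolarizationState("B", 40.0, 0.0),)),
            shape, modality="dispim", pad=0,
        )
        W = wigner_y90()
        rotated = W.apply(np.swapaxes(a.psf[0], 1, 3))
        assert np.abs(b.psf[0] - rotated).max() < 1e-8 * np.abs(rotated).max()


class TestFourierForms:
    @pytest.fixture(scope="class")
    def resp(self, config):
        return system_psf(
            config, preset_scheme("scheme6").for_view("A"), (8, 8, 8),
            modality="spim", pad=0,
        )

    def test_otf_dc_equals_spatial_sum(self, resp):
        for p in range(resp.n_measurements):
            for c in range(15):
                assert resp.otf[p, c, 0, 0, 0].real == pytest.approx(
                    resp.psf[p, c].sum(), rel=1e-10, abs=1e-9
                )

    def test_otf_hermitian(self, resp):
        # real PSF => full FFT Hermitian; rfft stores the non-redundant half,
        # so check axis-0/1 conjugate symmetry at the x-frequency edges
        import numpy.fft as fft

        full = fft.fftn(fft.ifftshift(resp.psf[0, 0]))
        flipped = np.conj(full[(-np.arange(8)) % 8][:, (-np.arange(8)) % 8][:, :, (-np.arange(8)) % 8])
        assert np.abs(full - flipped).max() < 1e-10 * np.abs(full).max()

    def test_back_projector_is_reflection(self, resp):
        back = make_back_projector(resp)
        n = 8
        # reflection in centered coordinates: c'[i] = c[(2*(n//2) - i) mod n]
        grid = (2 * (n // 2) - np.arange(n)) % n
        manual = resp.psf[:, :, grid][:, :, :, grid][:, :, :, :, grid]
        assert np.abs(back - manual).max() < 1e-10 * np.abs(manual).max()

    def test_adjoint_identity(self, resp, config):
        """<forward(x), y> = <x, backward(y)> on random 8^3 fields."""
        rng = np.random.default_rng(7)
        x = SHField(rng.normal(size=(15, 8, 8, 8)), config.voxel_size)
        y = rng.normal(size=(resp.n_measurements, 8, 8, 8))
        fx = np.stack(
            [v for v in _forward_no_clip(x, resp)]
        )
        meas = MeasurementSet(y, resp.entries, config.voxel_size)
        bty = back_project(meas, resp)
        lhs = np.sum(fx * y)
        rhs = np.sum(x.coeffs * bty)
        assert lhs == pytest.approx(rhs, rel=1e-8)


def _forward_no_clip(obj, resp):
    """Forward projection without the nonneg clip (pure linear operator)."""
    from scipy import fft as sp_fft

    F = sp_fft.rfftn(obj.coeffs, axes=(-3, -2, -1))
    for p in range(resp.n_measurements):
        spec = np.einsum("c...,c...->...", resp.otf[p], F)
        yield sp_fft.irfftn(spec, s=obj.shape, axes=(-3, -2, -1))
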