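import numpy as np
import pytest

from polodf.field import SHField
from polodf.psf import (
    AcquisitionScheme,
    OpticalConfig,
    PolarizationState,
    SystemResponse,
    preset_scheme,
    system_psf,
)
from polodf.reconstruct import (
    ReconstructionSettings,
    ResourceGuardError,
    egrl_dualview,
    egrl_iterate,
    egrl_precompute,
    egrl_reconstruct,
    egrlp_reconstruct,
    grl_reconstruct,
    rl_deconvolve,
    svd_eta_search,
    svd_factorize,
    svd_reconstruct,
)
from polodf.simulate import MeasurementSet, forward_project
from polodf.sphere import SphereGrid, sh_synthesize


class TestSettings:
    def test_iteration_defaults(self):
        s = ReconstructionSettings()
        assert s.n_iter(dual_view=True) == 10
        assert s.n_iter(dual_view=False) == 20

    def test_invalid_iterations(self):
        with pytest.raises(ValueError):
            ReconstructionSettings(iterations=0).n_iter(False)

    def test_eta_grid_spans_printed_range(self):
        s = ReconstructionSettings()
        assert s.eta_grid[0] == pytest.approx(1e-8)
        assert s.eta_grid[-1] == pytest.approx(1.0)
        ratios = s.eta_grid[1:] / s.eta_grid[:-1]
        assert np.allclose(ratios, 10**0.1)


class TestEGRL:
    def test_fixed_point_at_truth(self, small_setup, G):
        shell, resp, meas = small_setup
        st = ReconstructionSettings(iterations=1)
        ops = egrl_precompute(meas, resp, st)
        E = shell.coeffs.astype(float)
        E1 = egrl_iterate(E, ops, G, st)
        assert np.linalg.norm(E1 - E) / np.linalg.norm(E) < 1e-6

    def test_initialization_is_uniform_angular(self, small_setup):
        _, resp, meas = small_setup
        from polodf.reconstruct import _init_estimate

        E0 = _init_estimate([meas], 0, resp.work_shape, np.float64)
        assert np.allclose(E0[0], meas.volumes.sum(axis=0))
        assert np.abs(E0[1:]).max() == 0.0

    def test_matches_dense_restructured_oracle(self, small_setup, G):
        shell, resp, meas = small_setup
        st = ReconstructionSettings(iterations=3)
        sh_path = egrl_reconstruct(meas, resp, st, G)
        dense = grl_reconstruct(meas, resp, st, variant="restructured")
        rel = np.linalg.norm(sh_path.coeffs - dense.coeffs) / np.linalg.norm(
            sh_path.coeffs
        )
        assert rel < 1e-4

    def test_output_finite_and_clamped(self, small_setup, G):
        _, resp, meas = small_setup
        st = ReconstructionSettings(iterations=5)
        out = egrl_reconstruct(meas, resp, st, G)
        assert np.all(np.isfinite(out.coeffs))
        assert out.density.min() >= 0.0

    def test_dualview_grid_mismatch_rejected(self, config, G):
        scheme = preset_scheme("scheme6")
        ra = system_psf(config, scheme.for_view("A"), (8, 8, 8), pad=0)
        rb = system_psf(config, scheme.for_view("B"), (8, 8, 8), pad=2)
        meas = MeasurementSet(np.ones((3, 8, 8, 8)), ra.entries)
        with pytest.raises(ValueError):
            egrl_dualview(meas, meas, ra, rb)

    def test_scalar_restructured_rl_reduction(self, config):
        """With an l=0-only band and a single modulation, eGRL is exactly the
        restructured scalar RL iteration (verified against an independent
        plain-FFT implementation)."""
        shape = (16, 16, 16)
        scheme = AcquisitionScheme((PolarizationState("A", 30.0, 0.0),))
        resp = system_psf(config, scheme, shape, modality="spim", pad=0)
        resp.psf[:, 1:] = 0.0
        resp.otf[:, 1:] = 0.0
        rng = np.random.default_rng(0)
        c = np.zeros((15,) + shape)
        c[0, 5:11, 5:11, 5:11] = rng.uniform(50, 100, (6, 6, 6))
        meas = forward_project(SHField(c), resp)
        st = ReconstructionSettings(iterations=5, dv_ridge=0.0, freeze_rel=0.0)
        rec = egrl_reconstruct(meas, resp, st)
        scale = resp.psf[0, 0].sum()  # rl_deconvolve normalizes its PSF
        rl = rl_deconvolve(
            meas.volumes[0] / scale,
            resp.psf[0, 0],
            iterations=5,
            variant="restructured",
            init=meas.volumes[0],
        )
        assert np.abs(rec.density - rl).max() < 1e-6 * np.abs(rl).max()


class TestDenseGRL:
    def test_loglikelihood_monotone(self, small_setup):
        from polodf.simulate import add_poisson_noise

        _, resp, meas = small_setup
        noisy, _ = add_poisson_noise(meas, 1.0, seed=4)
        st = ReconstructionSettings(iterations=15)
        _, ll = grl_reconstruct(noisy, resp, st, variant="mlem", return_loglik=True)
        assert np.all(np.diff(ll) >= -1e-9 * np.abs(ll[0]))

    def test_resource_guard(self, config):
        scheme = preset_scheme("scheme6").for_view("A")
        resp = system_psf(config, scheme, (48, 48, 48), modality="spim", pad=0)
        meas = MeasurementSet(np.ones((3, 48, 48, 48)), resp.entries)
        with pytest.raises(ResourceGuardError):
            grl_reconstruct(meas, resp)

    def test_agrees_with_egrl_on_shapes(self, small_setup, G):
        """GRL (MLEM ordering) and eGRL (restructured ordering) are distinct
        iterations but converge to closely matching ODF fields."""
        from polodf.metrics import oncc, support_mask, ssim

        shell, resp, meas = small_setup
        st = ReconstructionSettings(iterations=20)
        dense = grl_reconstruct(meas, resp, st, variant="mlem")
        fast = egrl_reconstruct(meas, resp, st, G)
        grid = SphereGrid.fibonacci(500)
        mask = support_mask(shell.density)
        assert oncc(dense, fast, grid, mask) > 0.95
        assert ssim(dense.density, fast.density) > 0.99


class TestEGRLP:
    def test_deterministic(self, small_setup):
        _, resp, meas = small_setup
        st = ReconstructionSettings(iterations=4)
        a = egrlp_reconstruct(meas, resp, st)
        b = egrlp_reconstruct(meas, resp, st)
        assert np.array_equal(a.coeffs, b.coeffs)

    def test_worse_odf_recovery_than_egrl(self, config, G):
        """Decoupling density and orientation estimation (eGRL-p) degrades
        the ODF reconstruction relative to the joint eGRL estimate."""
        from polodf.metrics import oncc, support_mask
        from polodf.phantoms import make_double_helix

        shape = (32, 32, 32)
        truth = make_double_helix(shape)
        scheme = preset_scheme("scheme6")
        resp = system_psf(config, scheme, shape, modality="dispim", pad=8)
        meas = forward_project(truth, resp)
        st = ReconstructionSettings(iterations=10)
        joint = egrl_reconstruct(meas, resp, st, G)
        decoupled = egrlp_reconstruct(meas, resp, st, G)
        grid = SphereGrid.fibonacci(800)
        mask = support_mask(truth.density)
        assert oncc(truth, decoupled, grid, mask) < oncc(truth, joint, grid, mask)


class TestSVD:
    @pytest.fixture(scope="class")
    def setup(self, config):
        from polodf.phantoms import make_shell

        shape = (16, 16, 16)
        truth = make_shell(shape, radius=5.5, sigma=1.0)
        scheme = preset_scheme("scheme6")
        resp = system_psf(config, scheme, shape, modality="dispim", pad=0)
        meas = forward_project(truth, resp)
        return truth, resp, meas

    def test_factorization_residual(self, setup):
        _, resp, meas = setup
        system = svd_factorize([meas], [resp])
        # H = U diag(mu) V^h per frequency, on a random sample of frequencies
        otf = resp.otf.reshape(resp.n_measurements, 15, -1)
        rng = np.random.default_rng(5)
        for f in rng.integers(0, otf.shape[-1], size=20):
            A = otf[:, :, f]
            rebuilt = (system.u[f] * system.s[f]) @ system.vh[f]
            assert np.abs(A - rebuilt).max() < 1e-10 * max(np.abs(A).max(), 1e-12)

    def test_singular_values_sorted_nonnegative(self, setup):
        _, resp, meas = setup
        system = svd_factorize([meas], [resp])
        assert np.all(system.s >= 0)
        assert np.all(np.diff(system.s, axis=1) <= 1e-12)

    def test_noise_free_pseudoinverse_consistency(self, setup):
        """eta = 0 on noise-free data: re-projecting the estimate reproduces
        the measurements (the truth lies in the system's row space)."""
        _, resp, meas = setup
        est = svd_reconstruct(meas, resp, eta=0.0)
        re_meas = forward_project(
            SHField(est.coeffs, est.voxel_size), resp
        )
        err = np.abs(re_meas.volumes - meas.volumes).max()
        assert err < 1e-6 * meas.volumes.max()

    def test_tikhonov_limit_zero(self, setup):
        _, resp, meas = setup
        est = svd_reconstruct(meas, resp, eta=1e12)
        assert np.abs(est.coeffs).max() < 1e-6

    def test_negative_eta_rejected(self, setup):
        _, resp, meas = setup
        with pytest.raises(ValueError):
            svd_reconstruct(meas, resp, eta=-0.1)

    def test_eta_search_returns_grid_member(self, setup):
        truth, resp, meas = setup
        st = ReconstructionSettings(
            eta_grid=10.0 ** np.arange(-4.0, 0.1, 0.5)
        )
        eta, table = svd_eta_search(meas, resp, truth, st, SphereGrid.fibonacci(400))
        assert eta in st.eta_grid
        assert table.shape[1] == 2
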