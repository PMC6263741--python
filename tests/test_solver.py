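import numpy as np
import pytest

from dlpr.dictlearn import Dictionary
from dlpr.forward import backpropagate, generate_masks, observe
from dlpr.patches import PatchGrid, extract_patches, multiplicity_map, scatter_patches
from dlpr.solver import (
    DLPRConfig,
    dlpr,
    object_update,
    sensor_update_gaussian,
    sensor_update_noiseless,
    sensor_update_poisson,
)
from dlpr.evaluate import align_global_phase, rmse_phase
from .conftest import random_unit_atoms


def poisson_prox_objective(b, z, gamma, chi, absv):
    theta = np.maximum(b**2 * chi, 1e-300)
    return theta - z * np.log(theta) + (b - absv) ** 2 / gamma


def gaussian_prox_objective(b, z, gamma, sigma, absv):
    return (b**2 - z) ** 2 / sigma**2 + (b - absv) ** 2 / gamma


class TestPoissonSensorUpdate:
    def test_hand_value(self):
        u = sensor_update_poisson(np.array([2.0 + 0j]), np.array([4.0]), 1.0, 1.0)
        assert np.abs(u[0]) == pytest.approx(2.0)

    def test_small_gamma_keeps_magnitude(self, rng):
        v = rng.standard_normal(50) + 1j * rng.standard_normal(50)
        z = rng.integers(0, 10, 50).astype(float)
        u = sensor_update_poisson(v, z, 1e-12, 1.0)
        assert np.allclose(np.abs(u), np.abs(v), rtol=1e-5)

    def test_high_flux_exact_counts_give_sqrt_z_over_chi(self):
        chi = 1e8
        y = 7.3
        z = np.array([y * chi])
        u = sensor_update_poisson(np.array([1.0 + 1j]), z, 1.0, chi)
        assert np.abs(u[0]) == pytest.approx(np.sqrt(y), rel=1e-3)

    def test_phase_of_v_is_kept(self, rng):
        v = rng.standard_normal(20) + 1j * rng.standard_normal(20)
        u = sensor_update_poisson(v, np.ones(20), 2.0, 0.5)
        assert np.allclose(np.angle(u), np.angle(v))

    def test_minimizes_scalar_objective_on_grid(self, rng):
        for _ in range(50):
            absv = rng.uniform(0, 5)
            z = float(rng.integers(0, 20))
            gamma = 10 ** rng.uniform(-3, 3)
            chi = 10 ** rng.uniform(-3, 3)
            b = np.abs(sensor_update_poisson(np.array([absv + 0j]), np.array([z]), gamma, chi))[0]
            grid = np.linspace(0, 3 * max(absv, np.sqrt(z / chi)) + 1, 30_000)
            assert poisson_prox_objective(b, z, gamma, chi, absv) <= poisson_prox_objective(
                grid, z, gamma, chi, absv
            ).min() + 1e-6

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            sensor_update_poisson(np.array([1.0 + 0j]), np.array([-1.0]), 1.0, 1.0)


class TestNoiselessSensorUpdate:
    def test_idempotent_when_magnitude_matches(self, rng):
        v = rng.standard_normal(20) + 1j * rng.standard_normal(20)
        u = sensor_update_noiseless(v, np.abs(v) ** 2)
        assert np.allclose(u, v)

    def test_zero_intensity_gives_zero(self):
        assert sensor_update_noiseless(np.array([3j]), np.array([0.0]))[0] == 0

    def test_magnitude_replacement(self):
        u = sensor_update_noiseless(np.array([1j]), np.array([4.0]))
        assert u[0] == pytest.approx(2j)

    def test_zero_v_takes_zero_phase(self):
        u = sensor_update_noiseless(np.array([0j]), np.array([9.0]))
        assert u[0] == pytest.approx(3.0 + 0j)

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            sensor_update_noiseless(np.array([1j]), np.array([-1.0]))


class TestGaussianSensorUpdate:
    def test_small_gamma_keeps_magnitude(self, rng):
        v = rng.standard_normal(50) + 1j * rng.standard_normal(50)
        z = rng.uniform(-5, 20, 50)
        u = sensor_update_gaussian(v, z, 1e-12, 1.0)
        assert np.allclose(np.abs(u), np.abs(v), rtol=1e-4, atol=1e-8)

    def test_large_gamma_gives_sqrt_z(self):
        u = sensor_update_gaussian(np.array([1.0 + 0j]), np.array([9.0]), 1e12, 1.0)
        assert np.abs(u[0]) == pytest.approx(3.0, rel=1e-4)

    def test_root_of_depressed_cubic(self):
        """sigma^2/(2 gamma) = 1, z = 2, |v| = 3 -> b solves b^3 - b - 3 = 0."""
        b = np.abs(sensor_update_gaussian(np.array([3.0 + 0j]), np.array([2.0]), 0.5, 1.0))[0]
        roots = np.roots([1.0, 0.0, -1.0, -3.0])
        real_root = roots[np.abs(roots.imag) < 1e-9].real[0]
        assert b == pytest.approx(real_root, rel=1e-9)

    def test_zero_v_with_small_intensity_returns_zero(self):
        # C >= 0 at v = 0: the objective is minimized at b = 0
        u = sensor_update_gaussian(np.array([0j]), np.array([0.3]), 1.0, 2.0)
        assert u[0] == 0

    def test_zero_v_with_large_intensity_returns_positive_root(self):
        u = sensor_update_gaussian(np.array([0j]), np.array([9.0]), 10.0, 1.0)
        b = np.abs(u[0])
        assert b == pytest.approx(np.sqrt(9.0 - 0.05), rel=1e-6)

    def test_minimizes_scalar_objective_on_grid(self, rng):
        for _ in range(50):
            absv = rng.uniform(0, 5)
            z = rng.uniform(-5, 25)
            gamma = 10 ** rng.uniform(-3, 3)
            sigma = 10 ** rng.uniform(-2, 1)
            b = np.abs(
                sensor_update_gaussian(np.array([absv + 0j]), np.array([z]), gamma, sigma)
            )[0]
            grid = np.linspace(0, 3 * max(absv, np.sqrt(max(z, 0))) + 1, 30_000)
            assert gaussian_prox_objective(b, z, gamma, sigma, absv) <= gaussian_prox_objective(
                grid, z, gamma, sigma, absv
            ).min() + 1e-6


def dense_normal_equations(masks, grid, gamma, beta):
    """Explicit dense system matrix beta*gamma*sum A^H A + sum R^H R."""
    rows, cols = masks.image_shape
    n = rows * cols
    Fr = np.fft.fft(np.eye(rows), norm="ortho")
    Fc = np.fft.fft(np.eye(cols), norm="ortho")
    F2 = np.kron(Fr, Fc)  # row-major vectorization
    M = np.zeros((n, n), complex)
    As = []
    for s in range(masks.S):
        Ds = np.diag(np.exp(1j * masks.phases[s]).ravel())
        A = F2 @ Ds
        As.append(A)
        M += beta * gamma * (A.conj().T @ A)
    idx = grid.linear_indices()
    for patch in idx:
        R = np.zeros((patch.size, n))
        R[np.arange(patch.size), patch] = 1.0
        M += R.T @ R
    return M, As


class TestObjectUpdate:
    def test_solves_assembled_normal_equations(self, rng):
        masks = generate_masks(3, (8, 8), seed=11)
        grid = PatchGrid(w=3, image_shape=(8, 8))
        mu = multiplicity_map(grid).counts
        gamma, beta = 2.0, 0.05
        M, As = dense_normal_equations(masks, grid, gamma, beta)
        us = rng.standard_normal((3, 8, 8)) + 1j * rng.standard_normal((3, 8, 8))
        recon = rng.standard_normal((9, grid.n_patches)) + 1j * rng.standard_normal(
            (9, grid.n_patches)
        )
        numerator = scatter_patches(recon, grid)
        x = object_update(us, masks, numerator, mu, gamma, beta)
        rhs = beta * gamma * sum(
            As[s].conj().T @ us[s].ravel() for s in range(3)
        ) + numerator.ravel()
        res = np.linalg.norm(M @ x.ravel() - rhs) / np.linalg.norm(rhs)
        assert res < 1e-10

    def test_data_dominated_limit_is_mean_backprojection(self, rng):
        masks = generate_masks(4, (8, 8), seed=12)
        us = rng.standard_normal((4, 8, 8)) + 1j * rng.standard_normal((4, 8, 8))
        zero_mu = np.zeros((8, 8))
        x = object_update(us, masks, np.zeros((8, 8), complex), zero_mu, 1.0, 1.0)
        bp = sum(backpropagate(us[s], masks.phases[s]) for s in range(4)) / 4
        assert np.allclose(x, bp)

    def test_patch_dominated_limit_is_aggregation(self, rng):
        masks = generate_masks(3, (8, 8), seed=13)
        grid = PatchGrid(w=3, image_shape=(8, 8))
        mu = multiplicity_map(grid).counts
        recon = rng.standard_normal((9, grid.n_patches)) + 1j * rng.standard_normal(
            (9, grid.n_patches)
        )
        num = scatter_patches(recon, grid)
        us = rng.standard_normal((3, 8, 8)) + 1j * rng.standard_normal((3, 8, 8))
        x = object_update(us, masks, num, mu, 1e-14, 1.0)
        assert np.allclose(x, num / mu, rtol=1e-6)


class TestConfig:
    def test_poisson_defaults(self):
        g, b = DLPRConfig(mode="poisson", chi=1e-4).resolved_gamma_beta()
        assert g == pytest.approx(1e4)
        assert b == pytest.approx(1e-7)

    def test_gaussian_defaults(self):
        g, b = DLPRConfig(mode="gaussian", sigma=2.0).resolved_gamma_beta()
        assert g == pytest.approx(0.4)
        assert b == pytest.approx(0.0025)

    def test_poisson_requires_chi(self):
        with pytest.raises(ValueError):
            DLPRConfig(mode="poisson")

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            DLPRConfig(mode="noiseless", variant="hio")

    def test_atom_cap_default(self):
        assert DLPRConfig(mode="noiseless", w=10).resolved_max_atoms() == 30
        assert DLPRConfig(mode="noiseless", w=4).resolved_max_atoms() == 16


def small_problem(variant="gsf", mode="noiseless", size=24, S=12, seed=0, chi=None):
    from dlpr.scenes import make_test_suite

    scene = make_test_suite((size, size), seed=0)[1]  # constant amp, shear plane
    masks = generate_masks(S, (size, size), seed=seed + 1)
    level = chi
    obs = observe(scene.field, masks, mode, level, seed=seed + 2)
    kwargs = dict(mode=mode, variant=variant, S=S, w=6, k=24, T=4, eta=16, seed=seed)
    if mode == "poisson":
        kwargs["chi"] = chi
    return scene, masks, obs, kwargs


class TestDLPRLoop:
    def test_gsf_noiseless_converges(self):
        scene, masks, obs, kwargs = small_problem()
        cfg = DLPRConfig(iterations=150, **kwargs)
        x, D, hist = dlpr(obs, masks, cfg, truth=scene.field)
        assert D is None
        assert len(hist) == 150
        assert hist.rmse[-1] < 1e-3

    def test_dlpr_noiseless_converges_and_returns_dictionary(self):
        scene, masks, obs, kwargs = small_problem(variant="dlpr")
        cfg = DLPRConfig(iterations=100, **kwargs)
        x, D, hist = dlpr(obs, masks, cfg, truth=scene.field)
        assert isinstance(D, Dictionary)
        assert hist.rmse[-1] < 1e-2

    def test_noiseless_objective_nonincreasing_for_gsf(self):
        scene, masks, obs, kwargs = small_problem()
        cfg = DLPRConfig(iterations=40, **kwargs)
        _, _, hist = dlpr(obs, masks, cfg)
        diffs = np.diff(hist.objective)
        assert np.mean(diffs <= 1e-9 * max(1, abs(hist.objective[0]))) >= 0.95

    def test_forcing_patch_reconstruction_to_backprojection_reproduces_gsf(self, monkeypatch):
        """The ablation is exactly the full loop with the coded patches
        replaced by the half-step iterate."""
        scene, masks, obs, kwargs = small_problem(variant="dlpr")
        cfg = DLPRConfig(iterations=6, **kwargs)

        import dlpr.solver as solver_mod

        real_extract = solver_mod.extract_patches
        state = {}

        def capture_extract(x, grid):
            state["P"] = real_extract(x, grid)
            return state["P"]

        def fake_batch_omp(P, D, delta, max_atoms):
            return (np.full((1, P.shape[1]), -1, dtype=np.intp),
                    np.zeros((1, P.shape[1]), complex),
                    np.zeros(P.shape[1], dtype=np.intp),
                    np.zeros(P.shape[1]))

        def fake_reconstruct(D, supports, coefs):
            return state["P"]

        monkeypatch.setattr(solver_mod, "extract_patches", capture_extract)
        monkeypatch.setattr(solver_mod, "batch_omp", fake_batch_omp)
        monkeypatch.setattr(solver_mod, "reconstruct", fake_reconstruct)
        x_forced, _, _ = dlpr(obs, masks, cfg)
        monkeypatch.undo()

        cfg_gsf = DLPRConfig(iterations=6, **{**kwargs, "variant": "gsf"})
        x_gsf, _, _ = dlpr(obs, masks, cfg_gsf)
        assert np.allclose(x_forced, x_gsf, rtol=1e-12, atol=1e-12)

    def test_global_phase_rotation_of_init_leaves_aligned_error_unchanged(self):
        scene, masks, obs, kwargs = small_problem(variant="gsf")
        cfg = DLPRConfig(iterations=5, **kwargs)
        x0 = np.ones(scene.shape, complex) + 0.1j
        xa, _, _ = dlpr(obs, masks, cfg, x0=x0)
        xb, _, _ = dlpr(obs, masks, cfg, x0=x0 * np.exp(1j * 0.8))
        ra = rmse_phase(np.angle(align_global_phase(xa, scene.field)), scene.wrapped_phase)
        rb = rmse_phase(np.angle(align_global_phase(xb, scene.field)), scene.wrapped_phase)
        assert abs(ra - rb) < 1e-6

    def test_prior_plugged_requires_dictionary(self):
        scene, masks, obs, kwargs = small_problem(variant="prior_plugged")
        cfg = DLPRConfig(iterations=2, **kwargs)
        with pytest.raises(ValueError, match="prior"):
            dlpr(obs, masks, cfg)

    def test_prior_plugged_runs_with_supplied_dictionary(self, rng):
        scene, masks, obs, kwargs = small_problem(variant="prior_plugged")
        cfg = DLPRConfig(iterations=3, **kwargs)
        prior = Dictionary(atoms=random_unit_atoms(rng, 36, 24))
        x, D, hist = dlpr(obs, masks, cfg, prior=prior)
        assert np.allclose(D.atoms, prior.atoms, rtol=1e-12)
        assert len(hist) == 3

    def test_mode_mismatch_rejected(self):
        scene, masks, obs, kwargs = small_problem()
        cfg = DLPRConfig(iterations=2, **{**kwargs, "mode": "poisson", "chi": 1.0})
        with pytest.raises(ValueError, match="does not match"):
            dlpr(obs, masks, cfg)

    def test_poisson_mode_runs_and_improves_over_init(self):
        scene, masks, obs, kwargs = small_problem(variant="dlpr", mode="poisson", chi=10.0)
        cfg = DLPRConfig(iterations=30, **kwargs)
        x, D, hist = dlpr(obs, masks, cfg, truth=scene.field)
        assert hist.rmse[-1] < 0.2

    def test_gaussian_mode_runs(self):
        scene, masks, obs, kwargs = small_problem(variant="gsf", mode="noiseless")
        masks2 = generate_masks(12, scene.shape, seed=3)
        obs2 = observe(scene.field, masks2, "gaussian", 0.2, seed=4)
        # the default gamma = sigma^2/10 damps the sensor step 5x, so the
        # alternating projections need a few hundred iterations here
        cfg = DLPRConfig(mode="gaussian", variant="gsf", sigma=0.2, S=12, iterations=300, seed=0)
        x, _, hist = dlpr(obs2, masks2, cfg, truth=scene.field)
        assert hist.rmse[-1] < 0.2
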