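"""Stain vector estimation and (sparse) NMF factorization."""

import numpy as np
import pytest
from scipy.optimize import nnls
from sklearn.decomposition import NMF
from sklearn.linear_model import Lasso

import ihcnorm as ih
from ihcnorm.stains import (CANONICAL_DAB, CANONICAL_HEMATOXYLIN,
                            FactorizationResult, StainBasis, stain_order)
from ihcnorm.synth import default_basis

from conftest import basis_error_deg


def _scene_od(noise_sigma, seed=0):
    scene = ih.make_scene(ih.SynthConfig(noise_sigma=noise_sigma, seed=seed))
    return ih.image_to_od_matrix(scene.image), scene.true_basis.V


class TestMacenko:
    def test_recovers_basis_noiseless_within_1_degree(self):
        od, V0 = _scene_od(0.0)
        basis = ih.macenko_stain_vectors(od)
        assert basis_error_deg(basis.V, V0) < 1.0

    def test_recovers_basis_noisy_within_5_degrees(self):
        od, V0 = _scene_od(0.01)
        basis = ih.macenko_stain_vectors(od)
        assert basis_error_deg(basis.V, V0) < 5.0

    def test_recovery_error_monotone_in_noise(self):
        errs = []
        for sigma in (0.0, 0.01, 0.05):
            od, V0 = _scene_od(sigma, seed=3)
            errs.append(basis_error_deg(ih.macenko_stain_vectors(od).V, V0))
        assert errs[0] <= errs[1] <= errs[2]

    def test_single_stain_cloud_raises(self):
        rng = np.random.default_rng(0)
        od = np.outer(CANONICAL_HEMATOXYLIN, rng.uniform(0.2, 1.0, 500))
        with pytest.raises(ih.StainEstimationError):
            ih.macenko_stain_vectors(od)

    def test_too_few_pixels_raises(self):
        od = np.outer(CANONICAL_DAB, [0.5, 0.6])
        with pytest.raises(ih.StainEstimationError):
            ih.macenko_stain_vectors(od)

    def test_output_is_valid_basis(self):
        od, _ = _scene_od(0.01)
        basis = ih.macenko_stain_vectors(od)
        assert basis.V.min() >= 0
        assert np.allclose(np.linalg.norm(basis.V, axis=0), 1.0)


class TestSparseCode:
    def test_exact_representation_no_penalty(self):
        V = default_basis()
        od = 2.0 * V.V[:, [0]]
        s = ih.sparse_code(od, V, 0.0)
        assert s[:, 0] == pytest.approx([2.0, 0.0], abs=1e-9)

    def test_zero_pixel_codes_to_zero(self):
        V = default_basis()
        s = ih.sparse_code(np.zeros((3, 1)), V, 0.1)
        assert np.all(s == 0)

    def test_shrinkage_matches_grid_search_oracle(self):
        """Penalized solution agrees with a brute-force grid search over
        (s1, s2) in [0, 4]^2 at step 1e-3."""
        V = default_basis().V
        od = 2.0 * V[:, 0]
        lam = 0.1
        s = ih.sparse_code(od[:, None], V, lam)[:, 0]
        grid = np.arange(0, 4.0 + 1e-9, 1e-3)
        s1, s2 = np.meshgrid(grid, grid, indexing="ij")
        G = V.T @ V
        c = V.T @ od
        f = (0.5 * (od @ od) - c[0] * s1 - c[1] * s2
             + 0.5 * (G[0, 0] * s1 ** 2 + 2 * G[0, 1] * s1 * s2 + G[1, 1] * s2 ** 2)
             + lam * (s1 + s2))
        k = np.unravel_index(np.argmin(f), f.shape)
        best = np.array([grid[k[0]], grid[k[1]]])
        assert s[0] < 2.0 and s[1] == 0.0
        assert np.abs(s - best).max() < 2e-3

    @pytest.mark.parametrize("r", [2, 3])
    def test_matches_lasso_oracle_on_random_instances(self, r):
        """Coordinate-descent solution equals an independent positive-LASSO
        solver on random small instances."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            V = np.abs(rng.standard_normal((3, r)))
            V /= np.linalg.norm(V, axis=0)
            od = np.abs(rng.standard_normal(3))
            lam = float(rng.uniform(0.0, 0.3))
            s = ih.sparse_code(od[:, None], V, lam)[:, 0]
            if lam > 0:
                oracle = Lasso(alpha=lam / 3.0, positive=True,
                               fit_intercept=False, tol=1e-14,
                               max_iter=200_000).fit(V, od).coef_
            else:
                oracle, _ = nnls(V, od)
            assert np.abs(s - oracle).max() < 1e-3


class TestFactorization:
    def test_nmf_reconstructs_exact_factorizable_data(self):
        """On OD that is exactly a rank-2 non-negative product the
        factorization reproduces it (no quantization in the way)."""
        scene = ih.make_scene(ih.SynthConfig(noise_sigma=0.0))
        od = scene.true_basis.V @ scene.true_density
        res = ih.nmf_factorize(od, 2)
        err = np.linalg.norm(od - res.basis.V @ res.density) / np.linalg.norm(od)
        assert err < 1e-3

    def test_nmf_on_rendered_scene_reaches_quantization_floor(self):
        """On the uint8-rendered scene the residual is bounded by the
        quantization floor (measured with the generating basis itself)."""
        scene = ih.make_scene(ih.SynthConfig(noise_sigma=0.0))
        od = ih.image_to_od_matrix(scene.image)
        floor = np.linalg.norm(
            od - scene.true_basis.V @ ih.sparse_code(od, scene.true_basis, 0.0))
        res = ih.nmf_factorize(od, 2)
        ours = np.linalg.norm(od - res.basis.V @ res.density)
        assert ours <= 1.05 * floor

    def test_nmf_matches_reference_solver_error(self):
        """Reconstruction error comparable to an independent NMF solver."""
        od, _ = _scene_od(0.01)
        res = ih.nmf_factorize(od, 2)
        ours = np.linalg.norm(od - res.basis.V @ res.density)
        ref = NMF(n_components=2, init="nndsvda", tol=1e-6, max_iter=1000,
                  random_state=0).fit(od.T)
        theirs = np.linalg.norm(od.T - ref.transform(od.T) @ ref.components_)
        assert ours <= 1.05 * theirs + 1e-9

    def test_rank1_data_recovered_exactly(self):
        rng = np.random.default_rng(1)
        v = CANONICAL_DAB
        od = np.outer(v, rng.uniform(0.1, 1.0, 300))
        res = ih.snmf_factorize(od, 1, ih.SNMFParams(lambda_sparsity=0.0))
        err = np.linalg.norm(od - res.basis.V @ res.density) / np.linalg.norm(od)
        assert err < 1e-6
        assert basis_error_deg(res.basis.V, v[:, None]) < 0.01

    def test_objective_monotone_non_increasing(self):
        od, _ = _scene_od(0.01)
        for lam in (0.0, 0.1):
            res = ih.snmf_factorize(od, 2, ih.SNMFParams(lambda_sparsity=lam))
            diffs = np.diff(res.objective_history)
            assert np.all(diffs <= 1e-10)

    def test_snmf_with_zero_lambda_equals_nmf(self):
        od, _ = _scene_od(0.01)
        params = ih.SNMFParams(lambda_sparsity=0.0, seed=5)
        a = ih.snmf_factorize(od, 2, params)
        b = ih.nmf_factorize(od, 2, ih.SNMFParams(lambda_sparsity=0.7, seed=5))
        assert np.array_equal(a.basis.V, b.basis.V)
        assert np.array_equal(a.density, b.density)

    def test_sparsity_penalty_increases_zero_fraction(self):
        od, _ = _scene_od(0.01)
        dense = ih.nmf_factorize(od, 2).density
        sparse = ih.snmf_factorize(od, 2, ih.SNMFParams(lambda_sparsity=0.1)).density
        assert (sparse < 1e-10).mean() > (dense < 1e-10).mean()

    def test_snmf_recovers_basis_within_5_degrees(self):
        od, V0 = _scene_od(0.01)
        res = ih.snmf_factorize(od, 2)
        V = res.basis.V[:, stain_order(res.basis.V)]
        assert basis_error_deg(V, V0) < 5.0

    def test_result_is_valid(self):
        od, _ = _scene_od(0.01)
        res = ih.snmf_factorize(od, 2)
        assert isinstance(res, FactorizationResult)
        assert res.density.min() >= 0
        assert np.allclose(np.linalg.norm(res.basis.V, axis=0), 1.0)


class TestOrdering:
    def test_swapped_columns_are_restored(self):
        V = default_basis().V
        swapped = StainBasis(V[:, ::-1])
        assert np.array_equal(ih.order_stains(swapped).V, V)

    def test_idempotent_on_ordered_basis(self):
        basis = default_basis()
        assert np.array_equal(ih.order_stains(basis).V, basis.V)

    def test_small_rotations_keep_assignment(self):
        rng = np.random.default_rng(0)
        V = default_basis().V
        for _ in range(100):
            # random perturbation of each column by <= 20 degrees
            pert = V + np.tan(np.radians(rng.uniform(0, 20))) * \
                rng.standard_normal((3, 2)) * 0.3
            pert = np.clip(pert, 0, None)
            pert /= np.linalg.norm(pert, axis=0)
            ok = True
            for j in range(2):
                from conftest import angle_deg
                if angle_deg(pert[:, j], V[:, j]) > 20:
                    ok = False
            if not ok:
                continue
            assert np.array_equal(stain_order(pert), [0, 1])


def test_lambda_grid_search_returns_member_of_grid(default_scene):
    od = ih.image_to_od_matrix(default_scene.image[::4, ::4])
    best, errors = ih.stains.lambda_grid_search(od, 2, [0.0, 0.1])
    assert best in errors and set(errors) == {0.0, 0.1}
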