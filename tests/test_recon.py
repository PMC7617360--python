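"""MLEM / MAP-EM updates, penalty arithmetic and objective monotonicity."""

import numpy as np
import pytest
import scipy.sparse as sp

from bootpet.phantom import Sinogram
from bootpet.projector import Geometry, SystemModel, forward
from bootpet.recon import (
    MAPEM,
    MLEM,
    ReconConfig,
    log_likelihood,
    mapem_update,
    mlem_update,
    penalized_objective,
    quadratic_penalty,
    uniform_initializer,
)
from bootpet.weights import WeightMap, neighborhood_offsets, uniform_weights


def toy_system(matrix, image_shape, sinogram_shape):
    """System model with an explicit matrix (no PSF); adjoint by transpose."""
    geom = Geometry(
        n_angles=sinogram_shape[0], n_bins=sinogram_shape[1],
        bin_spacing_mm=1.0, image_shape=image_shape,
        voxel_spacing_mm=(1.0,) * len(image_shape),
    )
    mat = sp.csr_matrix(np.asarray(matrix, dtype=float))
    model = SystemModel(
        geometry=geom, psf_fwhm_mm=0.0, matrix=mat, matrix_t=mat.T.tocsr(),
        sensitivity=np.empty(image_shape), fov_mask=np.empty(image_shape, bool),
    )
    sens = (mat.T @ np.ones(mat.shape[0])).reshape(image_shape)
    model.sensitivity = sens
    model.fov_mask = sens > 0
    return model


def pair_weights(w01=1.0, w10=1.0):
    """1x2 grid with explicit weights between the two voxels."""
    offsets = neighborhood_offsets(2)
    w = np.zeros((9, 1, 2))
    w[offsets.index((0, 1)), 0, 0] = w01
    w[offsets.index((0, -1)), 0, 1] = w10
    return WeightMap(offsets=offsets, weights=w, symmetrized=(w01 == w10))


class TestMLEMUpdate:
    def test_scalar_fixed_point_algebra(self):
        """One voxel, one bin, coefficient 2, count 6: the ML solution is 3 and
        a single update from 1 reaches it."""
        system = toy_system([[2.0]], (1, 1), (1, 1))
        out = mlem_update(system, np.array([[1.0]]), np.array([[6]]))
        assert out[0, 0] == pytest.approx(3.0)
        # and 3 is the fixed point
        again = mlem_update(system, out, np.array([[6]]))
        assert again[0, 0] == pytest.approx(3.0)

    def test_noiseless_consistent_data_is_fixed_point(self, small_system, small_phantom):
        img = small_phantom.activity
        counts = forward(small_system, img)  # real-valued consistent data
        out = mlem_update(small_system, img, counts)
        mask = small_system.fov_mask & (img > 0)
        np.testing.assert_allclose(out[mask], img[mask], rtol=1e-10)

    def test_zero_voxels_stay_zero(self, small_system, small_sino, rng):
        img = rng.random(small_system.geometry.image_shape)
        img[::3] = 0.0
        out = img
        for _ in range(3):
            out = mlem_update(small_system, out, small_sino)
        assert (out[img == 0] == 0).all()

    def test_negative_image_rejected(self, small_system, small_sino):
        img = np.full(small_system.geometry.image_shape, -1.0)
        with pytest.raises(ValueError):
            mlem_update(small_system, img, small_sino)


class TestMLEMModel:
    def test_single_iteration_equals_one_update(self, small_system, small_sino):
        cfg = ReconConfig(n_iterations=1, post_smooth_fwhm_mm=0.0)
        res = MLEM(small_sino, small_system, cfg).fit()
        start = uniform_initializer(small_system, small_sino)
        np.testing.assert_allclose(
            res.values, mlem_update(small_system, start, small_sino), rtol=1e-12
        )

    def test_total_counts_convergence_noiseless(self, small_system, small_phantom):
        counts = forward(small_system, small_phantom.activity)
        sino = Sinogram(counts=counts, geometry=small_system.geometry, meta={})
        cfg = ReconConfig(n_iterations=30, post_smooth_fwhm_mm=0.0, record_objective=False)
        res = MLEM(sino, small_system, cfg).fit()
        target = counts.sum()
        start = forward(small_system, uniform_initializer(small_system, sino)).sum()
        final = forward(small_system, res.values).sum()
        assert abs(final - target) < abs(start - target)
        assert abs(final - target) / target < 1e-3

    def test_noise_amplified_at_low_counts(self, small_phantom, small_system):
        """Median NRMSE over seeds is worse at 5% than at 100% counts."""
        from bootpet.phantom import simulate_acquisition, thin_counts

        errs = {"full": [], "thin": []}
        truth = small_phantom.activity
        fov = small_system.fov_mask
        cfg = ReconConfig(record_objective=False)
        for seed in range(5):
            full = simulate_acquisition(truth, small_system, 10**6, seed=seed)
            thin = thin_counts(full, 0.05, seed=100 + seed)
            for tag, sino in (("full", full), ("thin", thin)):
                res = MLEM(sino, small_system, cfg).fit()
                est = res.values / sino.meta["scale"]
                errs[tag].append(
                    np.linalg.norm((est - truth)[fov]) / np.linalg.norm(truth[fov])
                )
        assert np.median(errs["thin"]) > np.median(errs["full"])

    def test_summary_mentions_settings(self, small_system, small_sino):
        cfg = ReconConfig(n_iterations=2, post_smooth_fwhm_mm=4.0)
        res = MLEM(small_sino, small_system, cfg).fit()
        s = res.summary()
        assert "MLEM" in s and "iterations" in s and "4 mm" in s


class TestQuadraticPenalty:
    def test_constant_image_zero(self):
        w = uniform_weights((6, 6))
        assert quadratic_penalty(np.full((6, 6), 3.7), w) == pytest.approx(0.0)

    def test_two_voxel_hand_value(self):
        w = pair_weights(1.0, 1.0)
        theta = np.array([[0.0, 2.0]])
        assert quadratic_penalty(theta, w) == pytest.approx(2.0)

    def test_matches_brute_force_double_loop(self, rng):
        shape = (6, 7)
        theta = rng.random(shape)
        w = uniform_weights(shape)
        expected = 0.0
        for j in np.ndindex(shape):
            for o in w.offsets:
                if o == (0, 0):
                    continue
                k = (j[0] + o[0], j[1] + o[1])
                if 0 <= k[0] < shape[0] and 0 <= k[1] < shape[1]:
                    expected += (1.0 / 9) * (theta[j] - theta[k]) ** 2
        expected *= 0.25
        assert quadratic_penalty(theta, w) == pytest.approx(expected, rel=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            quadratic_penalty(np.zeros((3, 3)), uniform_weights((4, 4)))


class TestPenalizedObjective:
    def test_beta_zero_is_loglik(self, small_system, small_sino, rng):
        img = rng.random(small_system.geometry.image_shape)
        w = uniform_weights(img.shape)
        assert penalized_objective(
            small_system, img, small_sino, w, 0.0
        ) == pytest.approx(log_likelihood(small_system, img, small_sino))

    def test_four_voxel_brute_force(self):
        system = toy_system(np.eye(4) + 0.1, (2, 2), (2, 2))
        img = np.array([[1.0, 2.0], [0.5, 3.0]])
        counts = np.array([[2, 1], [0, 4]])
        w = uniform_weights((2, 2))
        beta = 0.7
        proj = (system.matrix @ img.ravel()).reshape(2, 2)
        expected = float(np.sum(counts * np.log(proj) - proj))
        expected -= beta * quadratic_penalty(img, w)
        got = penalized_objective(system, img, counts, w, beta)
        assert got == pytest.approx(expected, rel=1e-10)


class TestMAPEMUpdate:
    def test_beta_zero_equals_mlem(self, small_system, small_sino, rng):
        img = rng.random(small_system.geometry.image_shape)
        w = uniform_weights(img.shape)
        a = mapem_update(small_system, img, small_sino, w, 0.0)
        b = mlem_update(small_system, img, small_sino)
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_huge_beta_shrinks_pairwise_differences(self):
        system = toy_system(np.eye(2) * 3.0, (1, 2), (1, 2))
        w = pair_weights(1.0, 1.0)
        theta = np.array([[1.0, 5.0]])
        counts = np.array([[3, 15]])
        out = mapem_update(system, theta, counts, w, beta=1e6)
        assert abs(out[0, 0] - out[0, 1]) < abs(theta[0, 0] - theta[0, 1])

    def test_negative_beta_and_asymmetric_weights_rejected(self, small_system, small_sino):
        img = np.ones(small_system.geometry.image_shape)
        w = uniform_weights(img.shape)
        with pytest.raises(ValueError):
            mapem_update(small_system, img, small_sino, w, -0.5)
        with pytest.raises(ValueError):
            mapem_update(small_system, img, small_sino, _asymmetric_map(img.shape), 1.0)

    def test_beta_continuity(self, small_system, small_sino, rng):
        img = rng.random(small_system.geometry.image_shape) + 0.1
        w = uniform_weights(img.shape)
        base = mapem_update(small_system, img, small_sino, w, 0.1)
        pert = mapem_update(small_system, img, small_sino, w, 0.1 + 1e-3)
        rel = np.linalg.norm(pert - base) / np.linalg.norm(base)
        assert rel < 1e-2


def _asymmetric_map(shape):
    w = uniform_weights(shape)
    bad = w.weights.copy()
    bad[0] *= 2.0  # break w_jk = w_kj
    return WeightMap(offsets=w.offsets, weights=bad, symmetrized=False)


class TestMAPEMModel:
    @pytest.mark.parametrize("beta", [0.01, 1.0])
    def test_penalized_objective_monotone(self, small_system, small_sino_thinned, beta):
        cfg = ReconConfig(n_iterations=40, post_smooth_fwhm_mm=0.0)
        w = uniform_weights(small_system.geometry.image_shape)
        res = MAPEM(small_sino_thinned, small_system, w, beta, cfg).fit()
        tr = res.objective_trace
        slack = 1e-8 * np.abs(tr).max()
        assert (np.diff(tr) >= -slack).all()
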