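"""Shape-model construction: mean, PCA scores, variation matrix, reconstruction."""

import logging

import numpy as np
import pytest

import cranioshape as cs
from cranioshape.errors import GridMismatchError, PoolSizeError
from cranioshape.shape_model import ShapePool

GRID_200 = cs.GridSpec((10, 5, 4))  # 200 voxels


def _random_pool(rng: np.random.Generator, n: int = 5,
                 grid: cs.GridSpec = GRID_200) -> ShapePool:
    rows = (rng.random((n, grid.n_voxels)) > 0.5).astype(np.float32)
    return ShapePool.from_matrix(rows, grid)


def _brute_force_pca(rows: np.ndarray, n_components: int):
    """Independent oracle: eigendecomposition of the centered covariance."""
    X = rows.astype(np.float64)
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:n_components]
    components = evecs[:, order]  # (N, d0)
    scores = Xc @ components  # (C, d0)
    return scores, components


def _sign_align(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Flip the columns of ``b`` to match the signs of ``a``."""
    signs = np.sign(np.sum(a * b, axis=0))
    signs[signs == 0] = 1.0
    return b * signs


class TestPoolBuilding:
    def test_identical_members_give_identical_rows(self, small_phantom):
        pool = cs.build_pool([small_phantom.copy() for _ in range(3)])
        assert np.array_equal(pool.warped[0], pool.warped[1])
        assert np.array_equal(pool.warped[1], pool.warped[2])

    def test_reference_row_is_its_own_flattened_data(self, small_pool, small_cohort):
        ref = small_cohort[small_pool.reference_index]
        assert np.array_equal(small_pool.warped[small_pool.reference_index],
                              ref.flatten().astype(np.float32))
        assert small_pool.transforms[small_pool.reference_index].is_identity()

    def test_warped_members_overlap_reference(self, small_pool):
        """Registration brings every cohort member close to the reference."""
        ref = small_pool.reference
        for row in small_pool.warped:
            warped = cs.from_flat(row, small_pool.grid)
            assert cs.dsc(warped, ref) >= 0.90

    def test_too_few_members_rejected(self, small_phantom):
        with pytest.raises(PoolSizeError):
            cs.build_pool([small_phantom])


class TestMeanShape:
    def test_identical_members_mean_is_the_member(self, small_phantom):
        pool = cs.build_pool([small_phantom.copy(), small_phantom.copy()])
        assert np.array_equal(cs.mean_shape(pool),
                              small_phantom.flatten().astype(np.float32))

    def test_single_voxel_disagreement_averages_to_half(self):
        a = np.zeros((2, 2, 2), np.float32)
        b = a.copy()
        b[0, 0, 0] = 1.0
        pool = ShapePool.from_matrix(
            np.vstack([a.reshape(1, -1), b.reshape(1, -1)]), cs.GridSpec((2, 2, 2))
        )
        mean = cs.mean_shape(pool)
        assert mean[0] == 0.5
        assert np.all(mean[1:] == 0)

    def test_mean_matches_independent_summation(self):
        rng = np.random.default_rng(1)
        pool = _random_pool(rng, n=6)
        # brute-force elementwise summation oracle
        acc = np.zeros(pool.grid.n_voxels)
        for row in pool.warped:
            for j, v in enumerate(row):
                acc[j] += v
        assert np.allclose(cs.mean_shape(pool), acc / pool.size)
        assert cs.mean_shape(pool).min() >= 0 and cs.mean_shape(pool).max() <= 1

    def test_mean_template_subset_semantics(self, small_phantom):
        pool = cs.build_pool([small_phantom.copy() for _ in range(3)])
        assert cs.mean_template(pool, subset_size=1) == small_phantom
        assert cs.mean_template(pool, subset_size=3) == small_phantom
        with pytest.raises(ValueError):
            cs.mean_template(pool, subset_size=0)
        with pytest.raises(ValueError):
            cs.mean_template(pool, subset_size=4)

    def test_nested_subset_templates_agree(self, small_pool):
        t_small = cs.mean_template(small_pool, subset_size=5)
        t_large = cs.mean_template(small_pool, subset_size=8)
        assert cs.dsc(t_small, t_large) >= 0.90


class TestVariations:
    def test_scores_and_variations_match_eigendecomposition_oracle(self):
        rng = np.random.default_rng(7)
        pool = _random_pool(rng, n=5)
        model = cs.fit_variations(pool, n_components=5)
        scores_o, _ = _brute_force_pca(pool.warped, 5)
        scores_o = _sign_align(model.scores, scores_o)
        assert np.max(np.abs(model.scores - scores_o)) < 1e-6
        variations_o = scores_o.T @ np.linalg.pinv(pool.warped.astype(np.float64)).T
        assert np.max(np.abs(model.variations - variations_o)) < 1e-6

    def test_projection_of_member_recovers_its_score_row(self):
        rng = np.random.default_rng(3)
        pool = _random_pool(rng, n=6)
        model = cs.fit_variations(pool)
        for i in range(pool.size):
            w = cs.project(model, pool.warped[i])
            assert np.max(np.abs(w.lambda_raw - model.scores[i])) < 1e-6

    def test_identical_members_give_zero_variations(self, small_phantom, caplog):
        pool = cs.build_pool([small_phantom.copy() for _ in range(3)])
        with caplog.at_level(logging.WARNING):
            model = cs.fit_variations(pool)
        assert np.all(model.variations == 0)
        assert "identical" in caplog.text

    def test_invalid_component_counts_rejected(self):
        pool = _random_pool(np.random.default_rng(0), n=4)
        with pytest.raises(ValueError):
            cs.fit_variations(pool, n_components=0)
        with pytest.raises(ValueError):
            cs.fit_variations(pool, n_components=5)

    def test_projection_length_mismatch_rejected(self):
        model = cs.fit_variations(_random_pool(np.random.default_rng(0)))
        with pytest.raises(GridMismatchError):
            cs.project(model, np.zeros(7))


class TestReconstruction:
    def test_modewise_and_matrix_reconstructions_agree(self):
        rng = np.random.default_rng(5)
        model = cs.fit_variations(_random_pool(rng, n=6))
        lam = rng.normal(size=model.n_components)
        a = cs.reconstruct_field(model, lam, mode="eq_mean_plus_variations")
        b = cs.reconstruct_field(model, lam, mode="inverse_pca")
        assert np.max(np.abs(a - b)) < 1e-8

    def test_zero_weights_reconstruct_the_mean(self):
        model = cs.fit_variations(_random_pool(np.random.default_rng(2)))
        out = cs.reconstruct(model, np.zeros(model.n_components))
        assert out == cs.from_flat(model.mean, model.grid, threshold=0.5)

    def test_variations_only_mode_omits_the_mean(self):
        rng = np.random.default_rng(9)
        model = cs.fit_variations(_random_pool(rng))
        lam = rng.normal(size=model.n_components)
        vonly = cs.reconstruct_field(model, lam, mode="variations_only")
        full = cs.reconstruct_field(model, lam, mode="inverse_pca")
        assert np.allclose(full - vonly, model.mean.astype(np.float64))

    def test_member_self_reconstruction_at_full_rank(self):
        """With all components retained, a member's own scores reproduce it."""
        phantoms = [
            cs.generate_phantom(cs.PhantomSpec(
                grid_shape=(32, 32, 32), radii=r, thickness=t))
            for r, t in [((12, 10, 11), 3.0), ((11.5, 10.5, 10.8), 3.4),
                         ((12.5, 9.8, 11.2), 2.8), ((11.8, 10.2, 11.5), 3.2),
                         ((12.2, 10.8, 10.6), 3.1)]
        ]
        rows = np.vstack([p.flatten() for p in phantoms]).astype(np.float32)
        pool = ShapePool.from_matrix(rows, phantoms[0].grid)
        model = cs.fit_variations(pool, n_components=pool.size)
        for i, phantom in enumerate(phantoms):
            recon = cs.reconstruct(model, model.scores[i])
            assert cs.dsc(recon, phantom) >= 0.98

    def test_more_components_never_increase_member_residuals(self):
        pool = _random_pool(np.random.default_rng(11), n=6)
        model_full = cs.fit_variations(pool, n_components=6)
        prev = np.inf
        for d0 in range(1, 7):
            model = cs.fit_variations(pool, n_components=d0)
            rss = 0.0
            for i in range(pool.size):
                recon = cs.reconstruct_field(model, model.scores[i])
                rss += float(np.sum((recon - pool.warped[i]) ** 2))
            assert rss <= prev + 1e-9
            prev = rss
        del model_full

    def test_unknown_mode_rejected(self):
        model = cs.fit_variations(_random_pool(np.random.default_rng(0)))
        with pytest.raises(ValueError, match="mode"):
            cs.reconstruct_field(model, np.zeros(model.n_components), mode="nope")


class TestWeights:
    def test_min_max_rescaling(self):
        assert np.allclose(cs.rescale_weights(np.array([2.0, 4.0, 6.0])),
                           [0.0, 0.5, 1.0])

    def test_constant_weights_rescale_to_zero(self, caplog):
        with caplog.at_level(logging.WARNING):
            out = cs.rescale_weights(np.array([3.0, 3.0, 3.0]))
        assert np.all(out == 0)
        assert "constant" in caplog.text


def test_model_persistence_round_trip(tmp_path, small_model):
    path = tmp_path / "model.npz"
    cs.save_model(small_model, path)
    back = cs.load_model(path)
    assert np.array_equal(back.mean, small_model.mean)
    assert np.array_equal(back.variations, small_model.variations)
    assert np.allclose(back.scores, small_model.scores)
    assert back.n_components == small_model.n_components
    assert back.grid == small_model.grid
    assert back.reference_volume == small_model.reference_volume
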