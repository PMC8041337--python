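"""Voxel-specific GLM, cluster permutation and the F-tail utility."""

import numpy as np
import pytest
from scipy.stats import f as f_dist, kstest

from sfcoupling.sfc import (F_EXACT_FIT, StructureFunctionModel, f_tail_p,
                            glm_contrast_stats, voxelwise_slope_f)
from sfcoupling.synthetic import make_ellipsoid_mask, make_symmetric_space


class TestFTailP:
    @pytest.mark.parametrize("F,df,expected,places", [
        (5.7, (1, 8), 0.044, 3),
        (0.13, (1, 8), 0.73, 2),
        (1.75, (1, 8), 0.22, 2),
        (1.02, (1, 8), 0.34, 2),
        (2.26, (1, 8), 0.17, 2),
    ])
    def test_reported_statistic_pairs(self, F, df, expected, places):
        assert round(f_tail_p(F, *df), places) == pytest.approx(expected)

    def test_zero_statistic_gives_one(self):
        assert f_tail_p(0.0, 1, 8) == 1.0
        assert f_tail_p(0.0, 3, 40) == 1.0

    def test_negative_statistic_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            f_tail_p(-1.0, 1, 8)


class TestVoxelwiseSlopeF:
    def test_exact_linear_relation_flagged(self):
        rng = np.random.default_rng(0)
        dens = rng.poisson(5, size=(10, 20)).astype(float)
        coh = 0.1 + 0.02 * dens
        F, beta, defined, exact = voxelwise_slope_f(coh, dens)
        ok = defined
        assert np.all(exact[ok])
        assert np.all(F[ok] == F_EXACT_FIT)
        assert np.allclose(beta[ok], 0.02)

    def test_null_quantiles_match_f_distribution(self):
        rng = np.random.default_rng(1)
        coh = rng.standard_normal((10, 5000))
        dens = rng.standard_normal((10, 5000))
        F, _, defined, _ = voxelwise_slope_f(coh, dens)
        assert kstest(F[defined], f_dist(1, 8).cdf).pvalue > 0.01

    def test_slope_sign_recovered(self):
        rng = np.random.default_rng(2)
        n_rep, hits = 40, 0
        for r in range(n_rep):
            x = rng.standard_normal((10, 1))
            y = 0.8 * x + 0.3 * rng.standard_normal((10, 1))
            _, beta, _, _ = voxelwise_slope_f(y, x)
            hits += beta[0] > 0
        assert hits / n_rep >= 0.95

    def test_affine_regressor_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((12, 200))
        y = rng.standard_normal((12, 200))
        F1, _, _, _ = voxelwise_slope_f(y, x)
        F2, _, _, _ = voxelwise_slope_f(y, -3.2 * x + 17.0)
        assert np.allclose(F1, F2, atol=1e-8, rtol=1e-8)

    def test_constant_regressor_undefined(self):
        y = np.random.default_rng(4).standard_normal((8, 3))
        x = np.ones((8, 3))
        F, beta, defined, _ = voxelwise_slope_f(y, x)
        assert not defined.any()
        assert np.all(np.isnan(F))

    def test_reduces_to_mass_univariate_glm_when_design_constant(self):
        # identical regressor image at every voxel -> classical GLM
        rng = np.random.default_rng(5)
        n, v = 12, 100
        x_col = rng.standard_normal(n)
        x = np.tile(x_col[:, None], (1, v))
        y = rng.standard_normal((n, v))
        F_vox, _, _, _ = voxelwise_slope_f(y, x)
        X = np.column_stack([np.ones(n), x_col])
        C = np.array([[0.0, 1.0]])
        F_glm, _, df = glm_contrast_stats(y, X, C)
        assert df == (1, n - 2)
        assert np.allclose(F_vox, F_glm, rtol=1e-10)


def _cohort(space, mask, rng, n=10, blob=None, coh_slope=0.5,
            dens_slope=25.0, coh_noise=0.015):
    m = np.asarray(mask.data) > 0
    levels = rng.uniform(0.2, 0.8, size=n)
    coh_imgs, dens_imgs = [], []
    for i in range(n):
        d = rng.poisson(5.0, size=space.shape).astype(float)
        c = rng.normal(0.3, coh_noise, size=space.shape)
        if blob is not None:
            d[blob] += dens_slope * levels[i]
            c[blob] += coh_slope * levels[i]
        d[~m] = 0
        c[~m] = np.nan
        coh_imgs.append(space.copy_with(c))
        dens_imgs.append(space.copy_with(d))
    return coh_imgs, dens_imgs


@pytest.fixture(scope="module")
def small_space():
    space = make_symmetric_space((12, 12, 12), 2.0)
    return space, make_ellipsoid_mask(space)


class TestStructureFunctionModel:
    def test_shape_mismatch_rejected(self, small_space):
        space, mask = small_space
        other = make_symmetric_space((10, 10, 10), 2.0)
        rng = np.random.default_rng(0)
        coh, dens = _cohort(space, mask, rng, n=4)
        dens[0] = other.copy_with(np.zeros(other.shape))
        with pytest.raises(ValueError, match="co-registered"):
            StructureFunctionModel(coh, dens)

    def test_all_constant_density_rejected(self, small_space):
        space, mask = small_space
        rng = np.random.default_rng(1)
        coh, _ = _cohort(space, mask, rng, n=5)
        dens = [space.copy_with(np.full(space.shape, 3.0))
                for _ in range(5)]
        with pytest.raises(ValueError, match="zero variance"):
            StructureFunctionModel(coh, dens, mask=mask)

    def test_undefined_voxels_excluded_from_f_image(self, small_space):
        space, mask = small_space
        rng = np.random.default_rng(2)
        coh, dens = _cohort(space, mask, rng, n=8)
        # make one in-mask voxel density-constant across observations
        vox = tuple(np.argwhere(np.asarray(mask.data) > 0)[0])
        for d in dens:
            d.data[vox] = 4.0
        res = StructureFunctionModel(coh, dens, mask=mask).fit()
        assert np.isnan(res.F_image.data[vox])

    def test_summary_mentions_df_and_voxels(self, small_space):
        space, mask = small_space
        rng = np.random.default_rng(3)
        coh, dens = _cohort(space, mask, rng, n=10)
        res = StructureFunctionModel(coh, dens, mask=mask).fit()
        s = res.summary()
        assert "(1, 8)" in s
        assert str(res.n_defined) in s


class TestClusterPermutation:
    def test_planted_blob_significant_and_reproducible(self, small_space):
        space, mask = small_space
        rng = np.random.default_rng(4)
        blob = (slice(5, 7),) * 3
        coh, dens = _cohort(space, mask, rng, n=10, blob=blob)
        res = StructureFunctionModel(coh, dens, mask=mask).fit()
        cl1 = res.cluster_permutation(forming_p=0.01, n_perm=200, seed=9)
        cl2 = res.cluster_permutation(forming_p=0.01, n_perm=200, seed=9)
        assert np.array_equal(cl1.p_fwe, cl2.p_fwe)
        sig = cl1.significant(alpha=0.01)
        assert sig.size >= 1
        labels = np.asarray(cl1.labels.data)
        blob_mask = np.zeros(space.shape, dtype=bool)
        blob_mask[blob] = True
        assert any(np.all(labels[blob_mask] == s) for s in sig)

    def test_fwe_p_floor_is_one_over_nperm_plus_one(self, small_space):
        space, mask = small_space
        rng = np.random.default_rng(5)
        blob = (slice(5, 7),) * 3
        coh, dens = _cohort(space, mask, rng, n=10, blob=blob)
        res = StructureFunctionModel(coh, dens, mask=mask).fit()
        cl = res.cluster_permutation(forming_p=0.01, n_perm=100, seed=0)
        assert np.all(cl.p_fwe >= 1.0 / 101.0)

    def test_fwe_p_nonincreasing_in_cluster_size(self, small_space):
        space, mask = small_space
        rng = np.random.default_rng(6)
        coh, dens = _cohort(space, mask, rng, n=10,
                            blob=(slice(4, 8),) * 3)
        res = StructureFunctionModel(coh, dens, mask=mask).fit()
        cl = res.cluster_permutation(forming_p=0.05, n_perm=150, seed=1)
        if cl.n_clusters >= 2:
            order = np.argsort(cl.sizes)
            assert np.all(np.diff(cl.p_fwe[order]) <= 1e-12)

    def test_empty_result_when_nothing_suprathreshold(self, small_space):
        space, mask = small_space
        rng = np.random.default_rng(7)
        coh, dens = _cohort(space, mask, rng, n=10)
        res = StructureFunctionModel(coh, dens, mask=mask).fit()
        cl = res.cluster_permutation(forming_p=1e-6, n_perm=100, seed=0)
        assert cl.n_clusters == 0
        assert cl.table().empty
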