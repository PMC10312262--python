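"""Permutation null, bootstrap reliability, and SVD alignment."""

from itertools import permutations

import numpy as np
import pytest
from scipy import stats

from connpls.pls import standardize
from connpls.resampling import (
    align_svd,
    bootstrap,
    bootstrap_ratio_threshold,
    exhaustive_permutation_test,
    permutation_test,
    procrustes_align,
)


def _bruteforce_perm_p(X, Y, n_top=None):
    """Oracle: enumerate all row permutations of X with plain numpy.

    Single group; standardization is a plain z-score, R a direct
    correlation, singular values via numpy on each permuted copy.
    """
    def svals(Xp):
        Zx = (Xp - Xp.mean(0)) / Xp.std(0, ddof=1)
        Zy = (Y - Y.mean(0)) / Y.std(0, ddof=1)
        R = Zy.T @ Zx / (Xp.shape[0] - 1)
        return -np.sort(-np.linalg.svd(R, compute_uv=False))

    s_obs = svals(X)
    null = np.array([svals(X[list(p)]) for p in permutations(range(X.shape[0]))])
    return s_obs, (null >= s_obs[None, :]).mean(axis=0)


class TestPermutation:
    def test_p_zero_when_observed_beats_every_permutation(self, planted_scaled):
        _, ds, _, _ = planted_scaled
        res = permutation_test(ds.X, ds.Y, ds.groups, n_perm=50, seed=0)
        assert res.p_perm[0] == 0.0

    def test_monte_carlo_converges_to_exhaustive_oracle(self, rng):
        X = rng.normal(size=(3, 4))
        Y = rng.normal(size=(3, 2))
        groups = np.repeat("young", 3).astype(object)
        s_obs, p_oracle = _bruteforce_perm_p(X, Y)
        mc = permutation_test(
            X, Y, groups, n_perm=3000, seed=42, group_order=("young",)
        )
        assert np.allclose(mc.observed_s, s_obs, atol=1e-10)
        assert np.allclose(mc.p_perm, p_oracle, atol=0.05)
        ex = exhaustive_permutation_test(X, Y, groups, group_order=("young",))
        assert np.allclose(ex.p_perm, p_oracle, atol=1e-12)

    def test_p_monotone_in_observed_singular_value(self, rng):
        # same null sample; a larger observed value can only lower p
        X = rng.normal(size=(20, 5))
        Y = rng.normal(size=(20, 2))
        groups = np.asarray(["young"] * 12 + ["old"] * 8, dtype=object)
        res = permutation_test(X, Y, groups, n_perm=200, seed=3)
        null1 = res.null_s[:, 0]
        for bump in (0.0, 0.1, 0.5):
            p_hi = np.mean(null1 >= res.observed_s[0] + bump)
            p_lo = np.mean(null1 >= res.observed_s[0])
            assert p_hi <= p_lo

    def test_same_seed_same_draws(self, rng):
        X = rng.normal(size=(16, 5))
        Y = rng.normal(size=(16, 2))
        groups = np.asarray(["young"] * 9 + ["old"] * 7, dtype=object)
        a = permutation_test(X, Y, groups, n_perm=50, seed=11)
        b = permutation_test(X, Y, groups, n_perm=50, seed=11)
        assert np.array_equal(a.null_s, b.null_s)

    def test_plus_one_estimator_never_zero(self, planted_scaled):
        _, ds, _, _ = planted_scaled
        res = permutation_test(ds.X, ds.Y, ds.groups, n_perm=20, seed=0, plus_one=True)
        assert res.p_perm[0] == pytest.approx(1 / 21)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="2 rows"):
            permutation_test(
                np.zeros((1, 2)), np.zeros((1, 1)),
                np.array(["young"], dtype=object), n_perm=5,
            )


class TestAlignment:
    def test_flip_and_identity(self, rng):
        ref = rng.normal(size=6)
        flipped, sign = align_svd(ref, -ref)
        assert sign == -1.0 and np.allclose(flipped, ref)
        same, sign = align_svd(ref, ref)
        assert sign == 1.0 and np.allclose(same, ref)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            align_svd(np.ones(3), np.zeros(3))

    def test_procrustes_fixes_swapped_degenerate_lvs(self, rng):
        ref = np.linalg.qr(rng.normal(size=(8, 2)))[0]
        swapped = ref[:, ::-1] * np.array([1.0, -1.0])
        aligned, Q = procrustes_align(ref, swapped)
        assert np.allclose(aligned, ref, atol=1e-10)
        assert np.allclose(Q @ Q.T, np.eye(2), atol=1e-12)


class TestBootstrap:
    def test_threshold_is_two_sided_95_normal_quantile(self):
        thr = bootstrap_ratio_threshold(0.95)
        assert thr == pytest.approx(stats.norm.ppf(0.975))
        assert round(thr, 2) == 1.96

    def test_planted_edge_exceeds_threshold(self, planted_scaled):
        _, ds, _, truth = planted_scaled
        out = bootstrap(ds.X, ds.Y, ds.groups, n_boot=200, seed=0, n_lv=1)
        top_edge = np.argmax(np.abs(np.asarray(truth.planted_lvs[0].v)))
        assert abs(out.bootstrap_ratio[0, top_edge]) > 1.96

    def test_zero_se_flagged_as_nan_not_inf(self):
        from connpls.resampling import BootstrapOutput

        out = BootstrapOutput(
            n_boot=2, threshold=1.96,
            v_se=np.array([[0.0, 1.0, 2.0]]),
            bootstrap_ratio=np.array([[np.nan, 1.0, 0.5]]),
            u_se=np.zeros((1, 2)),
            behavior_corr=np.zeros((1, 2)),
            behavior_corr_ci=np.zeros((1, 2, 2)),
        )
        assert np.isnan(out.bootstrap_ratio[0, 0])
        assert not np.isinf(out.bootstrap_ratio).any()
        assert np.array_equal(out.zero_se_edges(0), [0])

    def test_bootstrap_se_zero_handling_end_to_end(self, rng):
        # a column that is constant within a group kills the resample; the
        # run skips and counts it rather than emitting infinities
        groups = np.asarray(["young"] * 6 + ["old"] * 6, dtype=object)
        X = rng.normal(size=(12, 4))
        X[:6, 0] = np.array([1.0, 1.0, 1.0, 1.0, 1.0, 2.0])  # fragile column
        Y = rng.normal(size=(12, 2))
        out = bootstrap(X, Y, groups, n_boot=30, seed=2, n_lv=1)
        assert out.n_boot == 30
        assert not np.isinf(out.bootstrap_ratio[np.isfinite(out.bootstrap_ratio)]).any()
        assert out.n_skipped >= 0

    def test_same_seed_identical_output(self, rng):
        groups = np.asarray(["young"] * 10 + ["old"] * 8, dtype=object)
        X = rng.normal(size=(18, 6))
        Y = rng.normal(size=(18, 3))
        a = bootstrap(X, Y, groups, n_boot=40, seed=5, n_lv=2)
        b = bootstrap(X, Y, groups, n_boot=40, seed=5, n_lv=2)
        assert np.array_equal(a.bootstrap_ratio, b.bootstrap_ratio, equal_nan=True)
        assert np.array_equal(a.behavior_corr_ci, b.behavior_corr_ci)

    def test_behavior_corr_ci_covers_observed(self, planted_scaled):
        _, ds, _, _ = planted_scaled
        out = bootstrap(ds.X, ds.Y, ds.groups, n_boot=100, seed=1, n_lv=1)
        lo, hi = out.behavior_corr_ci[0, :, 0], out.behavior_corr_ci[0, :, 1]
        assert np.all(lo <= hi)
        # the strongest observed behavior correlation should sit inside its CI
        b = np.argmax(np.abs(out.behavior_corr[0]))
        assert lo[b] - 0.1 <= out.behavior_corr[0, b] <= hi[b] + 0.1

    def test_null_bootstrap_ratios_near_standard_normal(self):
        import connpls.synthetic as syn
        from conftest import TINY_NETWORKS

        cfg = syn.SyntheticConfig(
            n_young=70, n_old=50, networks=TINY_NETWORKS, seed=9
        )
        ds, _ = syn.simulate_null(cfg)
        out = bootstrap(ds.X, ds.Y, ds.groups, n_boot=1000, seed=9, n_lv=1)
        ratios = out.bootstrap_ratio[0]
        ratios = ratios[np.isfinite(ratios)]
        ks = stats.kstest(ratios, "norm").statistic
        assert ks < 0.2
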