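"""Standardization, cross-correlation, SVD decomposition, residualization."""

import numpy as np
import pytest

from connpls.pls import (
    brain_scores,
    cross_correlation,
    decompose,
    fit_pls,
    partial_corr_brainscores,
    residualize,
    standardize,
)


def _two_groups(n_young=8, n_old=6):
    return np.asarray(["young"] * n_young + ["old"] * n_old, dtype=object)


class TestStandardize:
    def test_single_group_column(self):
        z = standardize(np.array([[1.0], [2.0], [3.0]]), np.repeat("young", 3))
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0)

    def test_blocks_centered_separately(self, rng):
        groups = _two_groups()
        M = rng.normal(size=(14, 3))
        M[groups == "old"] += 50.0
        z = standardize(M, groups)
        for g in ("young", "old"):
            blk = z[groups == g]
            assert np.allclose(blk.mean(0), 0.0, atol=1e-12)
            assert np.allclose(blk.std(0, ddof=1), 1.0)

    def test_idempotent(self, rng):
        groups = _two_groups()
        M = rng.normal(size=(14, 4))
        once = standardize(M, groups)
        assert np.allclose(standardize(once, groups), once, atol=1e-12)

    def test_zero_variance_names_column_and_group(self):
        M = np.column_stack([np.ones(6), np.arange(6.0)])
        with pytest.raises(ValueError, match=r"\[0\].*'young'"):
            standardize(M, np.repeat("young", 6))


class TestCrossCorrelation:
    def test_shared_column_gives_unit_entry(self, rng):
        groups = np.repeat("young", 10).astype(object)
        X = rng.normal(size=(10, 3))
        Y = np.column_stack([X[:, 1], rng.normal(size=10)])
        R = cross_correlation(X, Y, groups, group_order=("young",))
        assert R[0, 1] == pytest.approx(1.0)

    def test_matches_per_pair_correlation_loop(self, rng):
        groups = _two_groups(30, 20)
        X = rng.normal(size=(50, 6))
        Y = rng.normal(size=(50, 2))
        R = cross_correlation(X, Y, groups)
        for gi, g in enumerate(("young", "old")):
            idx = np.flatnonzero(groups == g)
            for b in range(2):
                for e in range(6):
                    expected = np.corrcoef(Y[idx, b], X[idx, e])[0, 1]
                    assert R[gi * 2 + b, e] == pytest.approx(expected, abs=1e-12)

    def test_two_groups_five_behaviors_has_ten_rows(self, rng):
        groups = _two_groups()
        R = cross_correlation(rng.normal(size=(14, 7)), rng.normal(size=(14, 5)), groups)
        assert R.shape == (10, 7)

    def test_small_group_rejected(self, rng):
        groups = np.asarray(["young"] * 5 + ["old"] * 2, dtype=object)
        with pytest.raises(ValueError, match="'old'"):
            cross_correlation(rng.normal(size=(7, 3)), rng.normal(size=(7, 2)), groups)

    def test_positive_behavior_rescaling_leaves_R_unchanged(self, rng):
        groups = _two_groups()
        X = rng.normal(size=(14, 5))
        Y = rng.normal(size=(14, 3))
        R1 = cross_correlation(X, Y, groups)
        R2 = cross_correlation(X, Y * np.array([2.0, 17.0, 0.3]), groups)
        assert np.allclose(R1, R2, atol=1e-12)


class TestDecompose:
    def test_diagonal_case(self):
        lvs = decompose(np.array([[2.0, 0.0], [0.0, 1.0]]))
        assert [lv.s for lv in lvs] == [2.0, 1.0]
        assert [lv.cov_explained for lv in lvs] == pytest.approx([0.8, 0.2])

    def test_svd_identities(self, rng):
        R = rng.normal(size=(6, 20))
        lvs = decompose(R)
        U = np.column_stack([lv.u for lv in lvs])
        V = np.column_stack([lv.v for lv in lvs])
        s = np.array([lv.s for lv in lvs])
        assert np.allclose(U * s @ V.T, R, atol=1e-10)
        assert np.allclose(U.T @ U, np.eye(6), atol=1e-10)
        assert np.all(np.diff(s) <= 1e-12)

    def test_rank_one_planted_recovery(self, rng):
        u = rng.normal(size=5)
        u /= np.linalg.norm(u)
        v = rng.normal(size=12)
        v /= np.linalg.norm(v)
        lvs = decompose(3.0 * np.outer(u, v))
        assert lvs[0].s == pytest.approx(3.0)
        sign = np.sign(lvs[0].u @ u)
        assert np.allclose(sign * lvs[0].u, u, atol=1e-10)
        assert np.allclose(sign * lvs[0].v, v, atol=1e-10)

    def test_sign_convention_largest_u_entry_positive(self, rng):
        R = rng.normal(size=(4, 9))
        for lv in decompose(R):
            assert lv.u[np.argmax(np.abs(lv.u))] > 0

    def test_cov_explained_sums_to_one(self, rng):
        lvs = decompose(rng.normal(size=(10, 30)))
        assert sum(lv.cov_explained for lv in lvs) == pytest.approx(1.0, abs=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            decompose(np.array([[np.nan, 0.0]]))


class TestBrainScores:
    def test_projection_and_sign_covariance(self, rng):
        lvs = decompose(rng.normal(size=(2, 2)))
        lv = lvs[0]
        X = np.eye(2)
        assert np.allclose(brain_scores(X, lv), lv.v)
        lv_flipped = type(lv)(index=0, s=lv.s, cov_explained=lv.cov_explained,
                              u=-lv.u, v=-lv.v)
        assert np.allclose(brain_scores(X, lv_flipped), -lv.v)

    def test_dimension_mismatch(self, rng):
        lv = decompose(rng.normal(size=(2, 3)))[0]
        with pytest.raises(ValueError, match="edges"):
            brain_scores(np.zeros((4, 5)), lv)

    def test_noiseless_scores_track_planted_latents(self, noiseless_flat):
        # standardization is a group-specific affine map, so the match with
        # the raw planted latents is assessed within each group
        _, ds, truth = noiseless_flat
        lvs = fit_pls(ds.X, ds.Y, ds.groups)
        for g in ("young", "old"):
            idx = np.flatnonzero(ds.groups == g)
            r = np.corrcoef(
                lvs[0].brain_scores[idx], truth.latent_scores[idx, 0]
            )[0, 1]
            assert abs(r) > 0.999


class TestResidualize:
    def test_covariate_identical_to_column(self, rng):
        c = rng.normal(size=20)
        res = residualize(c.copy(), c)
        assert np.allclose(res, 0.0, atol=1e-10)

    def test_orthogonal_covariate_leaves_centered_column(self, rng):
        x = rng.normal(size=50)
        x -= x.mean()
        c = rng.normal(size=50)
        c -= c.mean()
        c -= (c @ x) / (x @ x) * x  # now orthogonal to x
        res = residualize(x, c)[:, 0]
        assert np.allclose(res, x, atol=1e-10)

    def test_matches_normal_equation_solve(self, rng):
        M = rng.normal(size=(30, 4))
        C = rng.normal(size=(30, 2))
        D = np.column_stack([np.ones(30), C])
        beta = np.linalg.solve(D.T @ D, D.T @ M)
        assert np.allclose(residualize(M, C), M - D @ beta, atol=1e-10)

    def test_rank_deficient_rejected(self, rng):
        c = rng.normal(size=10)
        with pytest.raises(ValueError, match="rank"):
            residualize(rng.normal(size=10), np.column_stack([c, 2 * c]))


class TestPartialCorrelation:
    def test_behavior_equals_scores(self, rng):
        s = rng.normal(size=30)
        c = rng.normal(size=30)
        r, p = partial_corr_brainscores(s, s.copy(), c)
        assert r == pytest.approx(1.0)

    def test_behavior_equals_covariate(self, rng):
        # residualizing the behavior on itself leaves numerical dust, so the
        # partial correlation is noise around zero rather than exactly zero
        s = rng.normal(size=30)
        c = rng.normal(size=30)
        r, _ = partial_corr_brainscores(s, c.copy(), c)
        assert abs(r) < 0.2

    def test_matches_inverse_correlation_formula(self, rng):
        n = 60
        s = rng.normal(size=n)
        b = 0.5 * s + rng.normal(size=n)
        C = rng.normal(size=(n, 2))
        r, _ = partial_corr_brainscores(s, b, C)
        P = np.linalg.inv(np.corrcoef(np.column_stack([s, b, C]).T))
        expected = -P[0, 1] / np.sqrt(P[0, 0] * P[1, 1])
        assert r == pytest.approx(expected, abs=1e-10)

    def test_too_few_rows_rejected(self, rng):
        with pytest.raises(ValueError, match="complete rows"):
            partial_corr_brainscores(
                np.arange(4.0), np.arange(4.0), rng.normal(size=(4, 2))
            )


class TestPipelineInvariances:
    def test_within_group_row_permutation_invariance(self, rng):
        groups = _two_groups(10, 8)
        X = rng.normal(size=(18, 6))
        Y = rng.normal(size=(18, 3))
        perm = np.arange(18)
        perm[:10] = rng.permutation(10)
        perm[10:] = 10 + rng.permutation(8)
        s1 = [lv.s for lv in decompose(cross_correlation(X, Y, groups))]
        s2 = [lv.s for lv in decompose(cross_correlation(X[perm], Y[perm], groups))]
        assert np.allclose(s1, s2, atol=1e-10)

    def test_noiseless_planted_recovery_up_to_sign(self, noiseless_flat):
        _, ds, truth = noiseless_flat
        lvs = fit_pls(ds.X, ds.Y, ds.groups)
        planted = truth.planted_lvs[0]
        v_p = np.asarray(planted.v)
        u_p = np.concatenate([planted.u_by_group["young"], planted.u_by_group["old"]])
        sign = np.sign(lvs[0].v @ v_p)
        assert abs(np.corrcoef(sign * lvs[0].v, v_p)[0, 1]) > 1 - 1e-9
        assert abs(np.corrcoef(sign * lvs[0].u, u_p)[0, 1]) > 1 - 1e-9
        assert lvs[0].cov_explained > 0.99
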