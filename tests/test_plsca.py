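"""PLSCA core: cross-correlation SVD, inertia identities, LOVO, permutation."""

import numpy as np
import pytest

import fallrisk as fr
from fallrisk.plsca import plsca_from_r

from conftest import make_table


def zblock(rng, n, p):
    x = rng.standard_normal((n, p))
    return (x - x.mean(0)) / x.std(0, ddof=1)


class TestCrossCorrelation:
    def test_self_correlation_is_one(self, rng):
        x = zblock(rng, 30, 1)
        assert fr.cross_correlation(x, x) == pytest.approx(np.array([[1.0]]))

    def test_entries_match_pearson(self, rng):
        x, y = zblock(rng, 25, 3), zblock(rng, 25, 4)
        r = fr.cross_correlation(x, y)
        for i in range(3):
            for j in range(4):
                assert r[i, j] == pytest.approx(np.corrcoef(x[:, i], y[:, j])[0, 1], abs=1e-10)

    def test_unstandardized_rejected(self, rng):
        x = rng.standard_normal((20, 2)) + 5.0
        with pytest.raises(ValueError, match="z-scored"):
            fr.cross_correlation(x, zblock(rng, 20, 2))

    def test_row_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="rows"):
            fr.cross_correlation(zblock(rng, 20, 2), zblock(rng, 21, 2))


class TestInertia:
    def test_single_row_r_inertia_is_row_norm(self):
        res = plsca_from_r(np.array([[0.6, 0.8]]))
        assert res.singular_values[0] == pytest.approx(1.0)
        assert res.inertia == pytest.approx(1.0)

    def test_untruncated_inertia_equals_frobenius(self, rng):
        # machine-precision identity on 100 random instances
        for _ in range(100):
            n = int(rng.integers(10, 40))
            x = zblock(rng, n, int(rng.integers(1, 5)))
            y = zblock(rng, n, int(rng.integers(2, 8)))
            res = fr.fit_plsca(x, y)
            r = fr.cross_correlation(x, y)
            assert res.inertia == pytest.approx(float(np.sum(r**2)), abs=1e-12)

    def test_group_indicator_self_inertia_one(self, rng):
        g = fr.zscore_vector(np.r_[np.ones(12), np.zeros(18)])
        assert fr.fit_plsca(g, g.copy()).inertia == pytest.approx(1.0)

    def test_invariant_to_column_permutation_and_sign(self, rng):
        x, y = zblock(rng, 30, 2), zblock(rng, 30, 5)
        base = fr.fit_plsca(x, y).inertia
        perm = rng.permutation(5)
        flipped = y[:, perm] * np.array([1, -1, 1, -1, 1])
        assert fr.fit_plsca(x, flipped).inertia == pytest.approx(base, abs=1e-12)

    def test_truncated_inertia_keeps_top_components(self, rng):
        x, y = zblock(rng, 40, 3), zblock(rng, 40, 6)
        res_full = fr.fit_plsca(x, y)
        res_k1 = fr.fit_plsca(x, y, k=1)
        assert res_k1.inertia == pytest.approx(res_full.singular_values[0] ** 2)
        assert res_k1.inertia <= res_full.inertia + 1e-12

    def test_degenerate_rejected(self, rng):
        x = zblock(rng, 20, 1)
        y = np.zeros((20, 2))
        with pytest.raises(ValueError):
            fr.fit_plsca(x, y)


class TestLovo:
    def test_analytic_column_norm_identity(self, rng):
        # brute-force refit equals the dropped column's squared norm in R
        for _ in range(20):
            n = int(rng.integers(15, 40))
            x = zblock(rng, n, 1)
            y = zblock(rng, n, int(rng.integers(2, 7)))
            lv = fr.lovo_importance(x, y)
            r = fr.cross_correlation(x, y)
            assert np.allclose(lv.importance, (r**2).ravel(), atol=1e-12)
            assert lv.importance.sum() == pytest.approx(lv.baseline_inertia, abs=1e-10)

    def test_worked_example(self):
        # R = [[0.6, 0.8]] -> untruncated LOVO importances (0.36, 0.64)
        n = 400
        rng = np.random.default_rng(0)
        x = zblock(rng, n, 1)
        e1, e2 = zblock(rng, n, 1), zblock(rng, n, 1)
        # construct y columns with exact sample correlations 0.6, 0.8 to x
        def with_r(e, target):
            resid = e - x * (x.T @ e).item() / (x.T @ x).item()
            resid = resid / resid.std(ddof=1)
            y = target * x + np.sqrt(1 - target**2) * resid
            return (y - y.mean()) / y.std(ddof=1)
        y = np.hstack([with_r(e1, 0.6), with_r(e2, 0.8)])
        lv = fr.lovo_importance(x, y)
        assert lv.importance == pytest.approx([0.36, 0.64], abs=1e-9)

    def test_duplicated_feature_equal_importance(self, rng):
        x = zblock(rng, 30, 1)
        col = zblock(rng, 30, 1)
        y = np.hstack([col, col.copy()])
        lv = fr.lovo_importance(x, y)
        assert lv.importance[0] == pytest.approx(lv.importance[1], abs=1e-12)

    def test_single_column_rejected(self, rng):
        with pytest.raises(ValueError):
            fr.lovo_importance(zblock(rng, 20, 1), zblock(rng, 20, 1))


class TestBetweenDomain:
    @pytest.mark.parametrize(
        "measured,pa,pb,expected",
        [(206.61, 11, 10, 9.84), (123.74, 10, 5, 8.25), (170.94, 5, 14, 9.00)],
    )
    def test_published_normalization(self, measured, pa, pb, expected):
        assert round(fr.normalize_inertia(measured, pa, pb), 2) == expected

    def test_identical_single_variable_blocks(self, rng):
        t = make_table(rng.standard_normal((20, 2)), domains=["balance", "gait"])
        a = t.subset(["v1"])
        b = make_table(a.values.copy(), domains=["gait"], group=t.group)
        measured, normalized = fr.between_domain_inertia(a, b)
        assert measured == pytest.approx(1.0, abs=1e-10)
        assert normalized == pytest.approx(0.5, abs=1e-10)


class TestPermutation:
    def test_copy_gives_minimal_p(self, rng):
        x = zblock(rng, 25, 2)
        p = fr.permutation_pvalue(x, x.copy(), b=99, seed=0)
        assert p == pytest.approx(1 / 100)

    def test_reproducible_and_valid_under_null(self, rng):
        x, y = zblock(rng, 30, 2), zblock(rng, 30, 3)
        p1 = fr.permutation_pvalue(x, y, b=199, seed=5)
        p2 = fr.permutation_pvalue(x, y, b=199, seed=5)
        assert p1 == p2
        assert 0 < p1 <= 1

    def test_too_few_permutations_rejected(self, rng):
        with pytest.raises(ValueError):
            fr.permutation_pvalue(zblock(rng, 20, 1), zblock(rng, 20, 2), b=10)


class TestLatentScores:
    def test_single_feature_proportional(self, rng):
        g = fr.zscore_vector(np.r_[np.ones(10), np.zeros(20)])
        y = zblock(rng, 30, 1)
        res = fr.fit_plsca(g, y)
        scores = fr.latent_scores(res, y)
        assert abs(np.corrcoef(scores, y[:, 0])[0, 1]) == pytest.approx(1.0)

    def test_orientation_toward_faller_coding(self, rng):
        yvec = np.r_[np.ones(15), np.zeros(15)]
        g = fr.zscore_vector(yvec)
        y = zblock(rng, 30, 4)
        y[:, 0] = g * 2 + 0.1 * y[:, 0]
        y = (y - y.mean(0)) / y.std(0, ddof=1)
        res = fr.fit_plsca(g, y)
        scores = fr.latent_scores(res, y, orient=yvec)
        assert np.corrcoef(scores, yvec)[0, 1] > 0

    def test_score_variance_matches_quadratic_form(self, rng):
        y = zblock(rng, 40, 5)
        g = zblock(rng, 40, 1)
        res = fr.fit_plsca(g, y)
        v1 = res.right_saliences[:, 0]
        scores = fr.latent_scores(res, y)
        direct = v1 @ (y.T @ y / (40 - 1)) @ v1
        assert np.var(scores, ddof=1) == pytest.approx(direct, abs=1e-10)
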