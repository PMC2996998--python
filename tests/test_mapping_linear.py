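import numpy as np
import pytest

from eqtlbench.io import GenotypeMatrix, MarkerMap
from eqtlbench.mapping import (
    CompositeIntervalMapper, HaleyKnottMapper, PenalizedMapper,
    map_cim, map_hk, map_penalized,
)


def _panel(X, spacing=1_000_000, chrom=None):
    n, p = X.shape
    chrom = chrom or ["chr1"] * p
    markers = MarkerMap(
        marker_id=np.array([f"m{i}" for i in range(p)], dtype=object),
        chromosome=np.array(chrom, dtype=object),
        position_bp=np.arange(1, p + 1) * spacing,
    )
    return GenotypeMatrix([f"s{i}" for i in range(n)], markers, X)


def _ols_lod_oracle(y, x):
    """Independent normal-equations oracle for the one-marker LOD."""
    n = len(y)
    X0 = np.ones((n, 1))
    X1 = np.column_stack([np.ones(n), x])
    rss0 = np.sum((y - X0 @ np.linalg.lstsq(X0, y, rcond=None)[0]) ** 2)
    rss1 = np.sum((y - X1 @ np.linalg.lstsq(X1, y, rcond=None)[0]) ** 2)
    rss1 = max(rss1, 1e-10 * rss0)
    return (n / 2) * np.log10(rss0 / rss1)


class TestHaleyKnott:
    def test_matches_ols_oracle_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(4, 21))
            p = int(rng.integers(2, 51))
            X = rng.integers(0, 2, (n, p)).astype(np.int8)
            y = rng.normal(size=n)
            prof = map_hk(y, _panel(X))
            want = [_ols_lod_oracle(y, X[:, j].astype(float)) for j in range(p)]
            assert np.max(np.abs(prof.scores - want)) < 1e-10

    def test_constant_trait_warns_all_zero(self):
        X = np.array([[0, 1], [1, 0], [1, 1], [0, 0]], dtype=np.int8)
        with pytest.warns(UserWarning, match="zero-variance"):
            prof = map_hk(np.ones(4), _panel(X))
        assert np.all(prof.scores == 0)

    def test_perfect_fit_hits_lod_floor(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 2, (12, 5)).astype(np.int8)
        y = X[:, 3].astype(float)  # trait equals a genotype exactly
        prof = map_hk(y, _panel(X))
        assert prof.scores[3] == pytest.approx(12 / 2 * 10)

    def test_marker_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        X = rng.integers(0, 2, (15, 20)).astype(np.int8)
        y = rng.normal(size=15)
        perm = rng.permutation(20)
        a = HaleyKnottMapper().fit(X, y).scores_
        b = HaleyKnottMapper().fit(X[:, perm], y).scores_
        assert np.allclose(a[perm], b, rtol=0, atol=1e-12)


class TestCIM:
    def test_zero_cofactors_equals_hk_bitwise(self):
        rng = np.random.default_rng(3)
        X = rng.integers(0, 2, (20, 30)).astype(np.int8)
        y = rng.normal(size=20)
        g = _panel(X)
        assert np.array_equal(map_cim(y, g, n_cofactors=0).scores,
                              map_hk(y, g).scores)

    def test_cofactor_self_exclusion_nonnegative(self):
        # 6-strain toy: the test marker that IS a cofactor must be excluded
        # from both models, so its LOD is an ordinary marginal LOD >= 0
        X = np.array([[1, 0, 1], [0, 1, 0], [1, 1, 1],
                      [0, 0, 0], [1, 0, 1], [0, 1, 1]], dtype=np.int8)
        y = np.array([2.0, 0.5, 2.5, 0.0, 2.2, 1.0])
        g = _panel(X, spacing=50_000_000)  # cofactors far apart
        est = CompositeIntervalMapper(marker_map=g.markers, n_cofactors=1).fit(X, y)
        assert est.cofactors_, "forward selection picked nothing"
        cof = est.cofactors_[0]
        assert est.scores_[cof] >= 0
        want = map_hk(y, g).scores[cof]
        assert est.scores_[cof] == pytest.approx(want, abs=1e-10)

    def test_distant_cofactor_matches_partial_regression_oracle(self):
        rng = np.random.default_rng(4)
        n = 30
        # two chromosomes: causal on chr1, cofactor signal on chr2
        X = rng.integers(0, 2, (n, 4)).astype(np.int8)
        chrom = ["chr1", "chr1", "chr2", "chr2"]
        y = 1.5 * X[:, 0] + 2.0 * X[:, 3] + rng.normal(0, 0.3, n)
        g = _panel(X, chrom=chrom)
        est = CompositeIntervalMapper(marker_map=g.markers, n_cofactors=1,
                                      window_bp=10_000_000).fit(X, y)
        cof = est.cofactors_[0]
        test_marker = 0 if cof != 0 else 1
        # oracle: LOD of test marker given the cofactor, via two lstsq fits
        ones = np.ones((n, 1))
        red = np.column_stack([ones, X[:, [cof]]])
        full = np.column_stack([red, X[:, [test_marker]]])
        rss_r = np.sum((y - red @ np.linalg.lstsq(red, y, rcond=None)[0]) ** 2)
        rss_f = np.sum((y - full @ np.linalg.lstsq(full, y, rcond=None)[0]) ** 2)
        want = (n / 2) * np.log10(rss_r / max(rss_f, 1e-10 * rss_r))
        assert est.scores_[test_marker] == pytest.approx(want, abs=1e-10)


class TestPenalized:
    def test_unpenalized_limit_equals_ols(self):
        # s = 1, lambda2 = 0, p < n, full rank -> |OLS coefficients|
        rng = np.random.default_rng(5)
        n, p = 40, 6
        X = rng.integers(0, 2, (n, p)).astype(np.int8)
        y = rng.normal(size=n) + X[:, 2]
        est = PenalizedMapper(lambda2=0.0, s_min=1.0, cv_folds=5, seed=0).fit(X, y)
        assert est.s_ == 1.0
        Xs = (X - X.mean(0)) / X.std(0)
        beta = np.linalg.lstsq(
            np.column_stack([np.ones(n), Xs]), y, rcond=None)[0][1:]
        assert np.max(np.abs(est.scores_ - np.abs(beta))) < 1e-8

    def test_lasso_equals_soft_threshold_on_orthonormal_toy(self):
        # single standardized predictor: lasso(lambda1) = sign(b)(|b|-lambda1/2)+
        rng = np.random.default_rng(6)
        n = 50
        x = rng.integers(0, 2, (n, 1)).astype(np.int8)
        y = 2.0 * x[:, 0] + rng.normal(0, 0.5, n)
        est = PenalizedMapper(lambda2=0.0, s_min=0.5, cv_folds=5, seed=0).fit(x, y)
        xs = (x[:, 0] - x[:, 0].mean()) / x[:, 0].std()
        b_ols = xs @ (y - y.mean()) / (xs @ xs)
        # at fraction s the lasso coefficient is exactly s * b_ols
        assert est.coef_[0] == pytest.approx(est.s_ * b_ols, rel=1e-8)

    def test_cv_never_selects_below_s_min(self):
        rng = np.random.default_rng(7)
        for seed in range(5):
            X = rng.integers(0, 2, (30, 40)).astype(np.int8)
            y = rng.normal(size=30)  # pure noise favours heavy shrinkage
            est = PenalizedMapper(lambda2=1.0, seed=seed, cv_folds=10).fit(X, y)
            assert est.s_ >= 0.5

    def test_constant_trait_warns(self):
        X = np.zeros((12, 5), dtype=np.int8)
        X[::2] = 1
        with pytest.warns(UserWarning, match="constant"):
            prof = map_penalized(np.full(12, 3.0), _panel(X), 0.0, cv_folds=4, seed=0)
        assert np.all(prof.scores == 0)

    def test_method_label_follows_lambda2(self):
        assert PenalizedMapper(lambda2=0.0).method == "LASSO"
        assert PenalizedMapper(lambda2=1.0).method == "ENET"
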