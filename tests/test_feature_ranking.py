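"""Weighting engines, ERFE, bootstrap schema, model-size choice and SAM."""

import numpy as np
import pytest
from scipy import stats

from grnbench.feature_ranking import (
    BootstrapSchema,
    MethodSpec,
    bootstrap_rank,
    choose_n_features,
    default_method,
    erfe_order,
    erfe_rank,
    sam_test,
    single_rank,
    size_grid,
    tune_hyperparams,
    weight_features,
)

METHODS = ("LSVM", "GSVM", "SRDA", "IRELIEF")


@pytest.fixture(scope="module")
def separable_toy():
    """One strongly informative feature among 50 noise features."""
    rng = np.random.default_rng(0)
    n = 40
    X = rng.standard_normal((n, 51))
    y = np.array([0] * 20 + [1] * 20)
    X[y == 1, 0] += 4.0
    return X, y


class TestTuning:
    def test_single_point_grid_returned_unchanged(self, separable_toy):
        X, y = separable_toy
        spec = MethodSpec("LSVM", grid={"c": (3.0,)})
        assert tune_hyperparams(spec, X, y, seed=0).c == 3.0

    def test_separable_toy_reaches_zero_cv_error(self):
        # wide-margin construction: the tuned c must achieve error 0
        rng = np.random.default_rng(7)
        n = 30
        X = rng.standard_normal((n, 10))
        y = np.array([0] * 15 + [1] * 15)
        X[y == 1, 0] += 10.0
        from grnbench.feature_ranking import _cv_error

        spec = tune_hyperparams(default_method("LSVM"), X, y, seed=0)
        assert _cv_error(spec, X, y, 3, 0) == 0.0

    def test_determinism(self, separable_toy):
        X, y = separable_toy
        a = tune_hyperparams(default_method("GSVM"), X, y, seed=5)
        b = tune_hyperparams(default_method("GSVM"), X, y, seed=5)
        assert (a.c, a.sigma) == (b.c, b.sigma)

    def test_degenerate_labels_rejected(self, separable_toy):
        X, _ = separable_toy
        with pytest.raises(ValueError):
            tune_hyperparams(default_method("LSVM"), X, np.zeros(len(X)), seed=0)


class TestWeighting:
    @pytest.mark.parametrize("name", METHODS)
    def test_informative_feature_gets_top_weight(self, separable_toy, name):
        X, y = separable_toy
        spec = tune_hyperparams(default_method(name), X, y, seed=1)
        w = weight_features(spec, X, y)
        assert w.shape == (51,)
        assert np.all(w >= 0)
        assert int(np.argmax(w)) == 0

    @pytest.mark.parametrize("name", ["LSVM", "SRDA", "IRELIEF"])
    def test_duplicated_columns_get_equal_weights(self, separable_toy, name):
        X, y = separable_toy
        Xd = np.hstack([X, X[:, [0]]])  # duplicate the informative column
        spec = default_method(name)
        w = weight_features(spec, Xd, y)
        assert np.isclose(w[0], w[-1], rtol=1e-4, atol=1e-8)

    def test_irelief_weights_unit_sum(self, separable_toy):
        X, y = separable_toy
        w = weight_features(default_method("IRELIEF"), X, y)
        assert np.isclose(w.sum(), 1.0)


class TestErfe:
    def test_ranking_is_a_permutation(self, separable_toy):
        X, y = separable_toy
        ranking, _ = erfe_order(default_method("LSVM"), X, y)
        assert sorted(ranking.tolist()) == list(range(51))

    def test_informative_feature_ranked_first(self, separable_toy):
        X, y = separable_toy
        for name in METHODS:
            spec = tune_hyperparams(default_method(name), X, y, seed=2)
            ranking, _ = erfe_order(spec, X, y)
            assert ranking[0] == 0, name

    def test_agrees_with_fixed_fraction_rfe_oracle(self, separable_toy):
        """ERFE and plain RFE agree on the top of a separable problem."""
        X, y = separable_toy
        # multi-feature variant: 3 informative features of graded strength
        rng = np.random.default_rng(4)
        X = X.copy()
        X[y == 1, 1] += 3.0
        X[y == 1, 2] += 2.0
        spec = tune_hyperparams(default_method("LSVM"), X, y, seed=0)
        erfe_ranking, _ = erfe_order(spec, X, y)

        # independent oracle: classical RFE, drop worst 20% per round
        active = np.arange(51)
        worst_first = []
        while len(active) > 1:
            w = weight_features(spec, X[:, active], y)
            k = max(1, int(0.2 * len(active)))
            order = np.argsort(w, kind="stable")
            worst_first.extend(active[order[:k]].tolist())
            active = active[order[k:]]
        worst_first.extend(active.tolist())
        rfe_ranking = worst_first[::-1]
        assert set(erfe_ranking[:3]) == set(rfe_ranking[:3]) == {0, 1, 2}

    def test_trivial_inputs(self):
        X = np.zeros((6, 1))
        y = np.array([0, 1, 0, 1, 0, 1])
        ranking, _ = erfe_order(default_method("LSVM"), X, y)
        assert ranking.tolist() == [0]

    def test_size_grid_covers_extremes(self):
        g = size_grid(100)
        assert g[0] == 1 and g[-1] == 100
        assert all(a < b for a, b in zip(g, g[1:]))


class TestModelSize:
    def test_minimum_and_tie_breaks(self):
        assert choose_n_features({10: 0.3, 20: 0.1, 40: 0.2}) == 20
        assert choose_n_features({10: 0.1, 20: 0.1}) == 10
        assert choose_n_features({10: 0.3, 20: 0.2, 40: 0.1}) == 40
        with pytest.raises(ValueError):
            choose_n_features({})


class TestRankingRuns:
    def test_single_run_contract(self, separable_toy):
        X, y = separable_toy
        run = single_rank(default_method("LSVM"), X, y, seed=3)
        assert len(run.ranking.ids) == 51
        assert run.selected == frozenset(run.ranking.ids[: run.n_star])
        assert run.error_curve[run.n_star] == min(run.error_curve.values())
        assert run.mcc_value is not None
        assert 0 in run.selected  # informative feature survives selection

    def test_bootstrap_reproducibility_and_quality(self, separable_toy):
        X, y = separable_toy
        schema = BootstrapSchema(B=8)
        a = bootstrap_rank(default_method("LSVM"), X, y, schema, seed=6)
        b = bootstrap_rank(default_method("LSVM"), X, y, schema, seed=6)
        assert a.ranking.ids == b.ranking.ids
        assert a.n_star == b.n_star
        assert a.ranking.ids[0] == 0  # informative feature aggregates to the top
        assert a.mcc_value > 0.8

    def test_erfe_rank_on_tiny_feature_set(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((12, 2))
        y = np.array([0, 1] * 6)
        run = erfe_rank(MethodSpec("LSVM", grid={"c": (1.0,)}), X, y, seed=0)
        assert sorted(run.ranking.ids) == [0, 1]


class TestSam:
    def test_power_construction_selects_the_shifted_genes(self):
        """Strongly shifted genes are always selected; spurious additions
        are rare (the median-FP estimate can admit the single strongest
        null gene when its own statistic clears every permutation)."""
        extras = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n, p = 40, 500
            y = np.array([0] * 20 + [1] * 20)
            X = rng.standard_normal((n, p))
            X[y == 1, :10] += 5.0
            res = sam_test(X, y, fdr=0.05, n_perm=150, seed=seed)
            assert frozenset(range(10)) <= res.selected  # full power
            extras.append(len(res.selected) - 10)
        assert np.median(extras) <= 1
        assert max(extras) <= 3

    def test_global_null_selects_nothing_in_median(self):
        sizes = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            X = rng.standard_normal((30, 400))
            y = rng.permutation(np.array([0] * 15 + [1] * 15))
            res = sam_test(X, y, fdr=0.05, n_perm=150, seed=seed)
            sizes.append(len(res.selected))
        assert np.median(sizes) == 0

    def test_s0_zero_matches_ordinary_t_ranking(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((30, 200))
        y = np.array([0] * 15 + [1] * 15)
        X[y == 1, :5] += 1.0
        res = sam_test(X, y, n_perm=100, seed=0, s0=0.0)
        t = stats.ttest_ind(X[y == 1], X[y == 0]).statistic
        assert np.array_equal(res.order, np.lexsort((np.arange(200), -np.abs(t))))

    def test_degenerate_labels_rejected(self):
        with pytest.raises(ValueError):
            sam_test(np.zeros((4, 3)), np.zeros(4))
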