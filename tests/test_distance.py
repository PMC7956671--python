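"""Synthetic augmentation, proximity/dissimilarity, VIMs, forest averaging."""

import numpy as np
import pandas as pd
import pytest

import oracles
from forestclust import (
    FeatureSchema,
    ForestParams,
    MixedTable,
    forest_distance,
    make_synthetic,
    scale_vims,
)
from forestclust.distance import (
    VimReport,
    compute_proximity,
    to_dissimilarity,
    vim_conditional,
    vim_unconditional,
)
from forestclust.forest import fit_forest_matrix

from conftest import make_random_table


class TestMakeSynthetic:
    def test_constant_column_stays_constant(self, rng):
        schema = [FeatureSchema("c", "continuous"), FeatureSchema("x", "continuous")]
        df = pd.DataFrame({"c": [3.0] * 10, "x": np.arange(10.0)})
        aug = make_synthetic(MixedTable(df, schema), rng)
        syn = aug.table.values["c"].to_numpy()[10:]
        assert (syn == 3.0).all()

    def test_structure_and_levels(self, rng):
        t = make_random_table(1, n=12)
        aug = make_synthetic(t, rng)
        assert aug.table.n == 24
        assert (aug.origin == np.r_[np.zeros(12), np.ones(12)]).all()
        np.testing.assert_array_equal(aug.real_index_map, np.arange(12))
        # synthetic categorical values are drawn from the observed real values
        for f in t.schema:
            if f.is_categorical:
                real = set(t.values[f.name])
                syn = set(aug.table.values[f.name][12:])
                assert syn <= real

    def test_missing_cells_rejected(self, rng):
        t = make_random_table(2, n=10, with_missing=True)
        with pytest.raises(ValueError, match="complete"):
            make_synthetic(t, rng)

    def test_destroys_cross_column_dependence(self):
        """Two perfectly correlated real columns become independent in the
        synthetic block (|r| < 0.08 at n = 2000)."""
        rng = np.random.default_rng(0)
        z = rng.normal(size=2000)
        schema = [FeatureSchema("a", "continuous"), FeatureSchema("b", "continuous")]
        t = MixedTable(pd.DataFrame({"a": z, "b": z}), schema)
        aug = make_synthetic(t, rng)
        syn = aug.table.values.iloc[2000:]
        r = np.corrcoef(syn["a"], syn["b"])[0, 1]
        assert abs(r) < 0.08

    @pytest.mark.parametrize("seed", range(12))
    def test_marginal_fidelity(self, seed):
        """Real and synthetic marginals agree: KS (continuous) and chi-square
        (categorical) tests are non-significant at alpha = 0.01."""
        from scipy import stats

        rng = np.random.default_rng(seed)
        n = 500
        schema = [
            FeatureSchema("x", "continuous"),
            FeatureSchema("g", "nominal", ("a", "b", "c", "d")),
        ]
        df = pd.DataFrame(
            {"x": rng.normal(size=n), "g": rng.choice(["a", "b", "c", "d"], n)}
        )
        aug = make_synthetic(MixedTable(df, schema), rng)
        real = aug.table.values.iloc[:n]
        syn = aug.table.values.iloc[n:]
        p_ks = stats.ks_2samp(real["x"], syn["x"]).pvalue
        tab = pd.crosstab(
            np.r_[np.zeros(n), np.ones(n)], aug.table.values["g"].to_numpy()
        )
        p_chi = stats.chi2_contingency(tab)[1]
        assert p_ks > 0.01 and p_chi > 0.01


class TestProximity:
    def test_single_leaf_forest_all_ones(self, rng):
        X = rng.normal(size=(15, 2))
        y = np.repeat([0, 1], [7, 8])
        f = fit_forest_matrix(
            X, y, np.zeros(2, bool), ForestParams(n_trees=4, max_depth=0, seed=0)
        )
        S = compute_proximity(f, X).S
        assert (S == 1.0).all()

    def test_arithmetic_of_the_counting_rule(self):
        """A pair co-terminal in 4 of 10 trees has proximity 0.4."""
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 3))
        y = np.repeat([0, 1], 10)
        f = fit_forest_matrix(X, y, np.zeros(3, bool), ForestParams(n_trees=10, seed=1))
        S = compute_proximity(f, X).S
        i, j = 0, 11
        count = sum(tree.route(X)[i] == tree.route(X)[j] for tree in f.trees)
        assert S[i, j] == pytest.approx(count / 10)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 24
        X = rng.normal(size=(n, 4))
        X[:, 3] = rng.integers(0, 3, n)
        y = np.repeat([0, 1], n // 2)
        nm = np.array([False, False, False, True])
        f = fit_forest_matrix(X, y, nm, ForestParams(n_trees=12, seed=seed))
        S = compute_proximity(f, X).S
        np.testing.assert_allclose(S, oracles.proximity_brute(f, X), atol=1e-12)
        assert np.allclose(np.diag(S), 1.0)
        assert np.allclose(S, S.T)
        assert S.min() >= 0 and S.max() <= 1

    def test_to_dissimilarity(self):
        from forestclust.distance import ProximityMatrix

        S = np.array(
            [
                [1.0, 0.25, 1.0, 0.5],
                [0.25, 1.0, 0.0, 0.1],
                [1.0, 0.0, 1.0, 0.3],
                [0.5, 0.1, 0.3, 1.0],
            ]
        )
        D = to_dissimilarity(ProximityMatrix(S, 4), np.array([0, 1]), ["a", "b"])
        assert D.D.shape == (2, 2)
        assert D.D[0, 1] == pytest.approx(0.75)
        assert D.D[0, 0] == 0.0
        D.validate()


class TestVims:
    def test_never_split_feature_exactly_zero(self):
        rng = np.random.default_rng(3)
        n = 60
        X = rng.normal(size=(n, 3))
        X[:, 2] = 5.0  # constant: never split on
        y = (X[:, 0] > 0).astype(int)
        f = fit_forest_matrix(
            X, y, np.zeros(3, bool), ForestParams(backend="RF", n_trees=15, seed=2)
        )
        imp = vim_unconditional(f, X, y, rng)
        assert imp[2] == 0.0

    def test_informative_feature_ranks_first(self):
        """A single strongly informative feature attains the top importance
        in at least 19 of 20 replicates."""
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            n = 80
            y = np.repeat([0, 1], n // 2)
            X = rng.normal(size=(n, 5))
            X[:, 1] = y + 0.3 * rng.normal(size=n)
            f = fit_forest_matrix(
                X, y, np.zeros(5, bool), ForestParams(backend="RF", n_trees=25, seed=seed)
            )
            imp = vim_unconditional(f, X, y, rng)
            wins += int(np.argmax(imp)) == 1
        assert wins >= 19

    def test_null_vims_centred_at_zero(self):
        """Pure-noise features have mean importance indistinguishable from 0
        (two-sided t-test at alpha = 0.01 over 60 replicates)."""
        from scipy import stats

        means = []
        for seed in range(60):
            rng = np.random.default_rng(500 + seed)
            n = 50
            X = rng.normal(size=(n, 4))
            y = np.repeat([0, 1], n // 2)
            rng.shuffle(y)
            f = fit_forest_matrix(
                X, y, np.zeros(4, bool), ForestParams(backend="RF", n_trees=10, seed=seed)
            )
            means.append(vim_unconditional(f, X, y, rng).mean())
        t = stats.ttest_1samp(means, 0.0)
        assert t.pvalue > 0.01

    def test_conditional_equals_unconditional_with_single_stratum(self):
        """A conditioner with one stratum makes the conditional permutation
        identical to the unconditional one (same rng stream)."""
        rng = np.random.default_rng(4)
        n = 50
        X = rng.normal(size=(n, 2))
        X[:, 1] = 2.0  # constant conditioner -> single stratum
        y = (X[:, 0] > 0).astype(int)
        f = fit_forest_matrix(
            X, y, np.zeros(2, bool), ForestParams(backend="RF", n_trees=8, seed=3)
        )
        vu = vim_unconditional(f, X, y, np.random.default_rng(99))
        vc = vim_conditional(f, X, y, np.random.default_rng(99))
        assert vc[0] == pytest.approx(vu[0])

    def test_scale_vims(self):
        r = scale_vims(VimReport(["a", "b", "c"], np.array([2.0, 1.0, 0.0])))
        np.testing.assert_allclose(r.scaled, [1.0, 0.5, 0.0])
        r0 = scale_vims(VimReport(["a", "b"], np.zeros(2)))
        np.testing.assert_allclose(r0.scaled, [0.0, 0.0])
        rn = scale_vims(VimReport(["a", "b", "c"], np.array([4.0, -1.0, 1.0])))
        np.testing.assert_allclose(rn.scaled, [1.0, 0.0, 0.25])
        # scaling preserves the ordering of the raw values (after clipping)
        assert list(np.argsort(rn.scaled)) == list(np.argsort(np.clip(rn.raw, 0, None)))


class TestCorrelatedImportance:
    """Behaviour of the two permutation schemes on the correlated design:
    a zero-coefficient feature riding a correlated block (X4) inherits
    unconditional importance, which the conditional scheme reduces."""

    def test_conditional_below_unconditional_for_correlated_null_feature(self):
        from forestclust import CorrelationSimSpec, simulate_correlation

        wins = 0
        reps = 8
        for rep in range(reps):
            s = 5000 + rep
            t = simulate_correlation(CorrelationSimSpec(seed=s))
            vu = np.zeros(12)
            vc = np.zeros(12)
            n_forests = 4
            for f_idx in range(n_forests):
                aug = make_synthetic(t, np.random.default_rng(s * 31 + f_idx))
                Xa, nm = aug.table.to_matrix()
                forest = fit_forest_matrix(
                    Xa, aug.origin, nm,
                    ForestParams(backend="condCIF", n_trees=25, cif_permutations=63,
                                 seed=s * 31 + f_idx),
                )
                vu += vim_unconditional(forest, Xa, aug.origin, np.random.default_rng(s + 7))
                vc += vim_conditional(forest, Xa, aug.origin, np.random.default_rng(s + 13))
            wins += vc[3] < vu[3]
        assert wins >= 7

    def test_pooled_vim_pattern_over_repetitions(self):
        """Across repetitions, the median unconditional importance of X4
        (beta = 0, correlated with X1..X3) lies within the interquartile
        range of the X1..X3 importances, and the uncorrelated X5..X7 stay
        below the X1..X4 medians."""
        from forestclust import CorrelationSimSpec, simulate_correlation
        from forestclust.distance import forest_distance as fd

        correlated = []
        x4 = []
        uncorrelated = []
        for rep in range(12):
            s = 7000 + rep
            t = simulate_correlation(CorrelationSimSpec(seed=s))
            res = fd(
                t,
                ForestParams(backend="RF", n_trees=30, seed=s),
                n_forests=3,
                seed=s,
                vim_mode="unconditional",
            )
            v = res.vims.raw
            correlated.extend(v[:3])
            x4.append(v[3])
            uncorrelated.extend(v[4:7])
        q1, q3 = np.percentile(correlated, [25, 75])
        assert q1 <= np.median(x4) <= q3
        assert np.median(uncorrelated) < np.median(np.r_[correlated, x4])


class TestForestDistance:
    def test_deterministic_and_valid(self, rng):
        t = make_random_table(5, n=16)
        t = MixedTable(t.values, t.schema, samples=t.samples)  # drop labels
        p = ForestParams(backend="RF", n_trees=6, seed=0)
        r1 = forest_distance(t, p, n_forests=3, seed=7, vim_mode="unconditional")
        r2 = forest_distance(t, p, n_forests=3, seed=7, vim_mode="unconditional")
        np.testing.assert_array_equal(r1.dissimilarity.D, r2.dissimilarity.D)
        np.testing.assert_array_equal(r1.vims.raw, r2.vims.raw)
        r1.dissimilarity.validate()
        assert r1.dissimilarity.n_forests == 3
        assert len(r1.oob_errors) == 3

    def test_monte_carlo_variance_shrinks_with_averaging(self):
        """The variance of dissimilarity entries across independent runs
        decreases with the number of averaged forests."""
        t = make_random_table(6, n=14)
        t = MixedTable(t.values, t.schema, samples=t.samples)
        p = ForestParams(backend="RF", n_trees=5, seed=0)

        def entry_variance(n_forests, n_runs=10):
            vals = []
            for s in range(n_runs):
                r = forest_distance(t, p, n_forests=n_forests, seed=1000 + s, vim_mode=None)
                vals.append(r.dissimilarity.D[0, 1:6])
            return np.var(np.array(vals), axis=0).mean()

        v1 = entry_variance(1)
        v5 = entry_variance(5)
        v25 = entry_variance(25)
        assert v5 < v1
        assert v25 < v5
        assert v1 / v25 > 5
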