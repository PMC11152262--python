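"""CART regression trees: split search, pre-pruning, rendering."""

import itertools

import numpy as np
import pandas as pd
import pytest

from elderwell.tree import CARTRegressor, best_split, grow_tree, predict_tree, render_tree


def brute_force_best_gain(X, y):
    """Exhaustive oracle: every binary partition expressible in the rule
    language (numeric thresholds; any non-trivial category subset)."""
    y = np.asarray(y, dtype=float)
    total = np.sum((y - y.mean()) ** 2)

    def sse(v):
        return np.sum((v - v.mean()) ** 2) if v.size else 0.0

    best = 0.0
    for col in X.columns:
        x = X[col]
        if pd.api.types.is_numeric_dtype(x) and not isinstance(x.dtype, pd.CategoricalDtype):
            xv = x.to_numpy(dtype=float)
            for t in np.unique(xv)[:-1]:
                mask = xv <= t
                best = max(best, total - sse(y[mask]) - sse(y[~mask]))
        else:
            levels = sorted(set(x.astype(str)))
            arr = x.astype(str).to_numpy()
            for r in range(1, len(levels)):
                for subset in itertools.combinations(levels, r):
                    mask = np.isin(arr, subset)
                    if mask.any() and (~mask).any():
                        best = max(best, total - sse(y[mask]) - sse(y[~mask]))
    return best


class TestBestSplit:
    def test_perfect_numeric_split(self):
        X = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]})
        y = [0.0, 0.0, 10.0, 10.0]
        cand = best_split(X, y)
        assert cand.variable == "x"
        assert 2.0 < cand.threshold < 3.0
        assert cand.gain == pytest.approx(100.0)
        assert cand.n_left == cand.n_right == 2

    def test_constant_outcome_returns_none(self):
        X = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        assert best_split(X, [5.0, 5.0, 5.0]) is None

    def test_dominant_predictor_chosen(self):
        rng = np.random.default_rng(0)
        sep = np.repeat([0, 1], 10)
        X = pd.DataFrame({"noise": rng.normal(size=20), "sep": sep.astype(float)})
        y = sep * 10.0 + rng.normal(scale=0.01, size=20)
        assert best_split(X, y).variable == "sep"

    def test_categorical_mean_ordering_is_optimal(self):
        X = pd.DataFrame({"c": ["a", "b", "c", "a", "b", "c", "a", "b"]})
        y = [0.0, 5.0, 10.0, 0.5, 5.5, 9.5, 0.2, 5.2]
        cand = best_split(X, y)
        assert cand.kind == "categorical"
        assert cand.gain == pytest.approx(brute_force_best_gain(X, y), abs=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_partition_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 30))
        X = pd.DataFrame(
            {
                "num": rng.normal(size=n),
                "bin": rng.integers(0, 2, n).astype(float),
                "cat": rng.choice(list("wxyz"), n),
            }
        )
        y = rng.normal(size=n) + 2.0 * X["bin"].to_numpy()
        cand = best_split(X, y)
        assert cand.gain == pytest.approx(brute_force_best_gain(X, y), abs=1e-9)


class TestGrowTree:
    def test_19_observations_single_leaf(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"x": rng.normal(size=19)})
        y = np.where(X["x"] > 0, 10.0, 0.0)  # strong signal, still no split
        tree = grow_tree(X, y, min_node=20)
        assert tree.is_leaf
        assert tree.proportion == 1.0

    def test_20_observations_may_split(self):
        X = pd.DataFrame({"x": np.arange(20, dtype=float)})
        y = np.where(X["x"] >= 10, 10.0, 0.0)
        tree = grow_tree(X, y, min_node=20)
        assert not tree.is_leaf

    def test_constant_outcome_single_leaf(self):
        X = pd.DataFrame({"x": np.arange(25, dtype=float)})
        tree = grow_tree(X, np.full(25, 0.7))
        assert tree.is_leaf and tree.mean == pytest.approx(0.7)

    def test_root_mean_is_sample_mean(self, paper_like_coded, paper_like_scores):
        X = paper_like_coded[["health_good", "learn_elderly", "class_total"]]
        est = CARTRegressor().fit(X, paper_like_scores["MWI_Quality"])
        keep = X.notna().all(axis=1) & paper_like_scores["MWI_Quality"].notna()
        assert est.tree_.mean == pytest.approx(
            paper_like_scores.loc[keep, "MWI_Quality"].mean(), abs=1e-12
        )

    def test_leaf_mass_and_mean_conservation(self, paper_like_coded, paper_like_scores):
        X = paper_like_coded[
            ["health_good", "learn_elderly", "class_total", "family_good", "working"]
        ]
        est = CARTRegressor(min_node=20).fit(X, paper_like_scores["MWI_Satisfaction"])

        leaves = []

        def collect(node):
            if node.is_leaf:
                leaves.append(node)
            else:
                collect(node.left)
                collect(node.right)

        collect(est.tree_)
        root = est.tree_
        assert sum(l.n for l in leaves) == root.n
        weighted = sum(l.n * l.mean for l in leaves) / root.n
        assert weighted == pytest.approx(root.mean, abs=1e-12)

    def test_raising_min_node_never_deepens(self, paper_like_coded, paper_like_scores):
        X = paper_like_coded[["health_good", "learn_elderly", "class_total", "family_good"]]
        y = paper_like_scores["MWI_Quality"]
        depths = [
            CARTRegressor(min_node=m, min_gain_frac=0.005).fit(X, y).tree_.depth()
            for m in (5, 10, 20, 40, 80)
        ]
        assert all(a >= b for a, b in zip(depths, depths[1:]))

    def test_deterministic(self, paper_like_coded, paper_like_scores):
        X = paper_like_coded[["health_good", "learn_elderly", "class_total"]]
        y = paper_like_scores["MWI_Quality"]
        r1 = CARTRegressor().fit(X, y).render()
        r2 = CARTRegressor().fit(X, y).render()
        assert r1 == r2

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            grow_tree(pd.DataFrame({"x": []}), [])

    def test_sklearn_cross_check_root_split(self):
        """Root threshold and child means agree with the reference CART
        implementation on a numeric problem."""
        from sklearn.tree import DecisionTreeRegressor

        rng = np.random.default_rng(4)
        X = pd.DataFrame({"a": rng.normal(size=120), "b": rng.normal(size=120)})
        y = (X["a"] > 0.3).astype(float) * 0.5 + rng.normal(scale=0.05, size=120)
        ours = grow_tree(X, y.to_numpy(), min_node=2, min_gain_frac=0.0)
        ref = DecisionTreeRegressor(max_depth=1, random_state=0).fit(X, y)
        assert ours.split.variable == X.columns[ref.tree_.feature[0]]
        # sklearn computes thresholds in float32, hence the looser tolerance
        assert ours.split.threshold == pytest.approx(ref.tree_.threshold[0], abs=1e-6)
        assert sorted([ours.left.mean, ours.right.mean]) == pytest.approx(
            sorted(ref.tree_.value.ravel()[1:]), abs=1e-9
        )


class TestRenderAndPredict:
    def test_single_leaf_label(self):
        X = pd.DataFrame({"x": [1.0] * 30})
        tree = grow_tree(X, np.full(30, 0.5))
        assert render_tree(tree) == "0.50 / 100%"

    def test_two_leaf_proportions_sum_to_100(self):
        X = pd.DataFrame({"x": np.arange(40, dtype=float)})
        y = np.where(X["x"] >= 20, 1.0, 0.0)
        text = render_tree(grow_tree(X, y))
        percents = [int(tok.rstrip("%")) for tok in text.split() if tok.endswith("%")]
        assert percents[0] == 100
        assert sum(percents[1:]) == 100

    def test_rule_text_uses_variable_level_naming(self, paper_like_coded, paper_like_scores):
        X = paper_like_coded[["learn_elderly"]]
        est = CARTRegressor(min_node=20, min_gain_frac=0.0).fit(
            X, paper_like_scores["MWI_Quality"]
        )
        if not est.tree_.is_leaf:
            assert est.tree_.split.describe() in ("learn_elderly_no", "learn_elderly_yes")

    def test_predict_returns_leaf_means(self):
        X = pd.DataFrame({"x": np.arange(40, dtype=float)})
        y = np.where(X["x"] >= 20, 1.0, 0.0)
        tree = grow_tree(X, y)
        preds = predict_tree(tree, X)
        assert set(np.round(preds, 6)) == {0.0, 1.0}

    def test_complete_case_drop_counted(self, paper_like_coded, paper_like_scores):
        X = paper_like_coded[["learn_elderly", "class_total"]]
        est = CARTRegressor().fit(X, paper_like_scores["MWI_Quality"])
        assert est.n_dropped_ == 8
        assert est.tree_.n == 292

    def test_json_round_trip(self, paper_like_coded, paper_like_scores):
        import json

        est = CARTRegressor().fit(
            paper_like_coded[["health_good", "class_total"]],
            paper_like_scores["MWI_Quality"],
        )
        d = json.loads(est.to_json())
        assert d["proportion"] == 1.0 and "mean" in d
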