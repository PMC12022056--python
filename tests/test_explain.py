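"""Shapley attributions: exactness vs brute force, local accuracy, importance ranking."""

from itertools import combinations
from math import factorial

import numpy as np
import pytest

from mscourse import (ModelSpec, global_importance, local_attribution, train)
from mscourse.explain import (PermutationShapleyExplainer, TreeShapleyExplainer)


def _data(seed=0, n=300, d=5):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, d))
    y = (X[:, 0] + 0.5 * X[:, 1] * X[:, 2] + 0.1 * rng.normal(size=n) > 0).astype(int)
    return X, y


def _cond_exp(tree, x, S, class_index, node=0):
    """Oracle value function: follow x on features in S, else cover-weighted average."""
    t = tree.tree_
    if t.children_left[node] == -1:
        v = t.value[node]
        if class_index is None:
            return float(v.ravel()[0])
        row = v[0]
        return float(row[class_index] / row.sum())
    f, th = int(t.feature[node]), t.threshold[node]
    if f in S:
        child = t.children_left[node] if x[f] <= th else t.children_right[node]
        return _cond_exp(tree, x, S, class_index, child)
    wn = t.weighted_n_node_samples
    wl = wn[t.children_left[node]] / wn[node]
    return (wl * _cond_exp(tree, x, S, class_index, t.children_left[node])
            + (1 - wl) * _cond_exp(tree, x, S, class_index, t.children_right[node]))


def _brute_shapley(trees, x, d, class_index, scale):
    """Exact Shapley by full subset enumeration of the value function above."""
    phi = np.zeros(d)
    for tree in trees:
        for i in range(d):
            others = [j for j in range(d) if j != i]
            for k in range(d):
                for S in combinations(others, k):
                    w = factorial(k) * factorial(d - k - 1) / factorial(d)
                    phi[i] += w * scale * (
                        _cond_exp(tree, x, set(S) | {i}, class_index)
                        - _cond_exp(tree, x, set(S), class_index))
    return phi


@pytest.mark.parametrize("kind,params", [
    ("random_forest", {"n_estimators": 4, "max_depth": 4}),
    ("gradient_boosting", {"n_estimators": 4, "max_depth": 3}),
])
def test_tree_attribution_matches_subset_enumeration(kind, params):
    X, y = _data(d=5)
    clf = train(ModelSpec(kind, hyperparameters=params, seed=0), X, y)
    explainer = TreeShapleyExplainer(clf)
    est = clf.estimator
    if kind == "random_forest":
        trees = est.estimators_
        ci, scale = int(np.flatnonzero(est.classes_ == 1)[0]), 1 / est.n_estimators
    else:
        trees = [t[0] for t in est.estimators_]
        ci, scale = None, est.learning_rate
    for x in X[:4]:
        mine = explainer.shap_values(x)[0]
        oracle = _brute_shapley(trees, x, 5, ci, scale)
        assert np.allclose(mine, oracle, atol=1e-10)


def test_local_accuracy_holds_for_every_visit():
    X, y = _data(n=200)
    clf = train(ModelSpec("random_forest",
                          hyperparameters={"n_estimators": 20, "max_depth": 5},
                          seed=1), X, y)
    explainer = TreeShapleyExplainer(clf)
    for x in X[:25]:
        att = explainer.attribution(x)  # AttributionVector asserts base + sum == output
        assert att.model_output == pytest.approx(
            clf.predict_proba(x.reshape(1, -1))[0, 1])


def test_constant_feature_gets_zero_attribution():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(300, 4))
    X[:, 2] = 7.0  # never split on -> null player
    y = (X[:, 0] > 0).astype(int)
    clf = train(ModelSpec("random_forest",
                          hyperparameters={"n_estimators": 10}, seed=0), X, y)
    phi = TreeShapleyExplainer(clf).shap_values(X[:10])
    assert np.allclose(phi[:, 2], 0.0)


def test_identical_visits_get_identical_attributions():
    X, y = _data(n=150)
    clf = train(ModelSpec("random_forest",
                          hyperparameters={"n_estimators": 10}, seed=0), X, y)
    ex = TreeShapleyExplainer(clf)
    a = ex.attribution(X[0]).contributions
    b = ex.attribution(X[0].copy()).contributions
    assert np.array_equal(a, b)


def test_global_importance_finds_planted_signal():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(400, 4))
    y = (X[:, 1] > 0).astype(int)  # label is a threshold on feature index 1
    clf = train(ModelSpec("random_forest",
                          hyperparameters={"n_estimators": 20}, seed=0), X, y)
    imp = global_importance(clf, X[:60], feature_names=["a", "b", "c", "d"])
    assert imp["feature"].iloc[0] == "b"


def test_importance_invariant_to_row_order_and_zero_for_constant():
    rng = np.random.default_rng(6)
    X = rng.normal(size=(200, 3))
    X[:, 2] = 1.0
    y = (X[:, 0] > 0).astype(int)
    clf = train(ModelSpec("random_forest",
                          hyperparameters={"n_estimators": 10}, seed=0), X, y)
    rows = X[:40]
    i1 = global_importance(clf, rows, ["a", "b", "c"])
    i2 = global_importance(clf, rows[::-1], ["a", "b", "c"])
    assert list(i1["feature"]) == list(i2["feature"])
    assert np.allclose(i1["mean_abs_contribution"], i2["mean_abs_contribution"])
    assert i1.set_index("feature").loc["c", "mean_abs_contribution"] == 0.0


def test_non_tree_model_requires_sampling_opt_in():
    X, y = _data(n=100, d=3)
    clf = train(ModelSpec("logistic_regression", seed=0), X, y)
    with pytest.raises(ValueError, match="random_forest"):
        local_attribution(clf, X[0])
    att = local_attribution(clf, X[0], allow_sampling=True, background=X[:20], seed=0)
    assert att.model_output == pytest.approx(clf.predict_proba(X[:1])[0, 1])


def test_permutation_explainer_is_seeded_and_exactly_additive():
    X, y = _data(n=120, d=4)
    clf = train(ModelSpec("svm_rbf", seed=0), X, y)
    ex1 = PermutationShapleyExplainer(clf, X[:15], n_permutations=8, seed=42)
    ex2 = PermutationShapleyExplainer(clf, X[:15], n_permutations=8, seed=42)
    a1, a2 = ex1.attribution(X[0]), ex2.attribution(X[0])
    assert np.array_equal(a1.contributions, a2.contributions)
    # local accuracy is asserted inside AttributionVector at construction
    assert a1.base_value + a1.contributions.sum() == pytest.approx(a1.model_output)
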