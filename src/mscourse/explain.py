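"""Shapley additive feature attributions for the fitted classifiers.

Attributions explain the model's SPMS output for a single visit as a sum of
signed per-feature contributions around a base value (the model's expected
output), so positive values push toward SPMS and negative toward RRMS --
the force-plot convention.  Local accuracy (base + sum of contributions =
model output) holds exactly for every attribution and is asserted at
construction.

Two engines are provided:

* :class:`TreeShapleyExplainer` -- exact path-dependent Shapley values for
  tree ensembles (random forest: SPMS probability; gradient boosting:
  log-odds margin).  For each leaf, the conditional value function
  factorizes over the unique features on its root path (a feature
  contributes its split-indicator when "present" and its product of node
  cover ratios when "absent"), which reduces the Shapley sum to weighted
  elementary symmetric polynomials computed in O(path length^2) per leaf.
* :class:`PermutationShapleyExplainer` -- a seeded interventional
  permutation-sampling estimator for arbitrary probabilistic models (SVM,
  logistic regression), used behind an explicit opt-in because it is slower
  and only approximates the exact Shapley values (local accuracy still
  holds exactly, by telescoping within each permutation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier

from .models import ProbabilisticClassifier

TREE_KINDS = ("random_forest", "gradient_boosting")


@dataclass(frozen=True)
class AttributionVector:
    features: tuple[str, ...]
    contributions: np.ndarray   # signed, positive toward SPMS
    base_value: float
    model_output: float         # SPMS probability (RF) or log-odds margin (GB)

    def __post_init__(self) -> None:
        total = self.base_value + float(np.sum(self.contributions))
        if abs(total - self.model_output) > 1e-6:
            raise AssertionError(
                f"local accuracy violated: base + sum = {total}, output = {self.model_output}")

    def as_series(self) -> pd.Series:
        return pd.Series(self.contributions, index=list(self.features))


# ---------------------------------------------------------------------------
# exact tree-path attribution
# ---------------------------------------------------------------------------

@dataclass
class _Leaf:
    value: float                # contribution to the ensemble output
    features: np.ndarray        # unique feature ids on the root path
    lo: np.ndarray              # open lower bounds (x > lo)
    hi: np.ndarray              # closed upper bounds (x <= hi)
    zero_frac: np.ndarray       # per-feature product of cover ratios
    cover: float                # leaf cover / root cover


def _extract_leaves(tree, scale: float, class_index: Optional[int]) -> list[_Leaf]:
    """Flatten one fitted sklearn tree into per-leaf path summaries."""
    t = tree.tree_
    leaves: list[_Leaf] = []

    def value_at(node: int) -> float:
        v = t.value[node]
        if class_index is None:          # regression tree (gradient boosting stage)
            return float(v.ravel()[0]) * scale
        row = v[0]
        return float(row[class_index] / row.sum()) * scale

    root_cover = t.weighted_n_node_samples[0]

    def walk(node: int, constraints: dict[int, tuple[float, float, float]]) -> None:
        if t.children_left[node] == -1:
            feats = np.array(sorted(constraints), dtype=int)
            lo = np.array([constraints[f][0] for f in feats])
            hi = np.array([constraints[f][1] for f in feats])
            zf = np.array([constraints[f][2] for f in feats])
            leaves.append(_Leaf(value_at(node), feats, lo, hi, zf,
                                t.weighted_n_node_samples[node] / root_cover))
            return
        f = int(t.feature[node])
        th = float(t.threshold[node])
        wn = t.weighted_n_node_samples
        for child, is_left in ((t.children_left[node], True), (t.children_right[node], False)):
            lo, hi, zf = constraints.get(f, (-np.inf, np.inf, 1.0))
            ratio = wn[child] / wn[node]
            if is_left:
                new = (lo, min(hi, th), zf * ratio)
            else:
                new = (max(lo, th), hi, zf * ratio)
            walk(child, {**constraints, f: new})

    walk(0, {})
    return leaves


def _leaf_shapley(leaf: _Leaf, x: np.ndarray, phi: np.ndarray) -> None:
    """Accumulate one leaf's exact Shapley contributions into ``phi``.

    The leaf's conditional value function is
    ``v(S) = value * prod_{i in S} hit_i * prod_{i not in S} zero_frac_i``
    over its unique path features, so the Shapley sum collapses to weighted
    elementary symmetric polynomials of the zero-fractions of the features
    that ``x`` satisfies.
    """
    k = len(leaf.features)
    if k == 0 or leaf.value == 0.0:
        return
    xv = x[leaf.features]
    hits = (xv > leaf.lo) & (xv <= leaf.hi)
    p = leaf.zero_frac
    hit_idx = np.flatnonzero(hits)
    miss_idx = np.flatnonzero(~hits)
    h = len(hit_idx)
    pz_all = float(np.prod(p[miss_idx])) if len(miss_idx) else 1.0

    # elementary symmetric polynomials e_0..e_h of {p_i : i hit}
    e = np.zeros(h + 1)
    e[0] = 1.0
    for pi in p[hit_idx]:
        e[1:h + 1] = e[1:h + 1] + pi * e[0:h]
    # Shapley weights s!(k-1-s)!/k! for coalition sizes s = 0..k-1
    w = np.array([_shapley_weight(s, k) for s in range(k)])

    for j in miss_idx:
        pz = pz_all / p[j]
        w_j = pz * float(np.dot(w[:h + 1], e[h::-1]))
        phi[leaf.features[j]] += leaf.value * (0.0 - p[j]) * w_j
    for j in hit_idx:
        # deflate e by feature j: divide the generating polynomial by (1 + p_j t)
        ed = np.zeros(h)
        if h:
            ed[0] = 1.0
            for r in range(1, h):
                ed[r] = e[r] - p[j] * ed[r - 1]
        w_j = pz_all * float(np.dot(w[:h], ed[h - 1::-1])) if h else pz_all * w[0]
        phi[leaf.features[j]] += leaf.value * (1.0 - p[j]) * w_j


_FACT_CACHE: dict[tuple[int, int], float] = {}


def _shapley_weight(s: int, k: int) -> float:
    key = (s, k)
    if key not in _FACT_CACHE:
        from math import factorial
        _FACT_CACHE[key] = factorial(s) * factorial(k - 1 - s) / factorial(k)
    return _FACT_CACHE[key]


class TreeShapleyExplainer:
    """Exact Shapley attributions for RF (SPMS probability) and GB (log-odds)."""

    def __init__(self, model: ProbabilisticClassifier,
                 feature_names: Optional[Sequence[str]] = None):
        est = model.estimator
        self.model = model
        if isinstance(est, RandomForestClassifier):
            class_index = int(np.flatnonzero(est.classes_ == 1)[0])
            scale = 1.0 / est.n_estimators
            self._leaves = [leaf for t in est.estimators_
                            for leaf in _extract_leaves(t, scale, class_index)]
            self.output_kind = "probability"
            self._offset = 0.0
        elif isinstance(est, GradientBoostingClassifier):
            lr = est.learning_rate
            self._leaves = [leaf for stage in est.estimators_
                            for leaf in _extract_leaves(stage[0], lr, None)]
            self.output_kind = "margin"
            # constant initial raw prediction; recover it from any point
            x0 = np.zeros((1, est.n_features_in_))
            raw = float(est.decision_function(x0)[0])
            trees = sum(lr * t[0].predict(x0)[0] for t in est.estimators_)
            self._offset = raw - trees
        else:
            raise TypeError(
                "exact tree attribution supports random_forest and gradient_boosting; "
                f"got {type(est).__name__} (use PermutationShapleyExplainer for others)")
        self.base_value = self._offset + float(
            sum(leaf.value * leaf.cover for leaf in self._leaves))
        self.n_features = est.n_features_in_
        self.feature_names = tuple(feature_names) if feature_names is not None else tuple(
            f"f{i}" for i in range(self.n_features))

    def _output(self, x: np.ndarray) -> float:
        est = self.model.estimator
        if self.output_kind == "probability":
            return float(self.model.predict_proba(x.reshape(1, -1))[0, 1])
        return float(est.decision_function(x.reshape(1, -1))[0])

    def shap_values(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.zeros((X.shape[0], self.n_features))
        for r, x in enumerate(X):
            phi = out[r]
            for leaf in self._leaves:
                _leaf_shapley(leaf, x, phi)
        return out

    def attribution(self, x: np.ndarray) -> AttributionVector:
        phi = self.shap_values(x)[0]
        return AttributionVector(self.feature_names, phi, self.base_value,
                                 self._output(np.asarray(x, dtype=float)))


# ---------------------------------------------------------------------------
# sampling fallback for non-tree models
# ---------------------------------------------------------------------------

class PermutationShapleyExplainer:
    """Seeded interventional permutation-sampling Shapley estimator.

    The value of a coalition S is the model's mean SPMS probability over the
    background set with the features in S replaced by the explained visit's
    values.  Each sampled permutation telescopes from the background to the
    full visit, so attributions sum exactly to output - base even at small
    sample counts; more permutations only reduce the variance of the split
    between features.
    """

    def __init__(self, model: ProbabilisticClassifier, background: np.ndarray,
                 n_permutations: int = 32, seed: int = 0,
                 feature_names: Optional[Sequence[str]] = None):
        self.model = model
        self.background = np.atleast_2d(np.asarray(background, dtype=float))
        self.n_permutations = n_permutations
        self.seed = seed
        d = self.background.shape[1]
        self.n_features = d
        self.feature_names = tuple(feature_names) if feature_names is not None else tuple(
            f"f{i}" for i in range(d))
        self.base_value = float(self.model.predict_proba(self.background)[:, 1].mean())

    def attribution(self, x: np.ndarray) -> AttributionVector:
        x = np.asarray(x, dtype=float).ravel()
        d = self.n_features
        rng = np.random.default_rng(self.seed)
        perms = [rng.permutation(d) for _ in range(self.n_permutations)]
        B = self.background
        # states: for each perm, d+1 progressive replacements, each over the background
        blocks = []
        for perm in perms:
            z = np.repeat(B[None, :, :], d + 1, axis=0)  # (d+1, n_bg, d)
            for step, j in enumerate(perm):
                z[step + 1:, :, j] = x[j]
            blocks.append(z)
        stacked = np.concatenate(blocks, axis=0).reshape(-1, d)
        vals = self.model.predict_proba(stacked)[:, 1].reshape(
            self.n_permutations, d + 1, B.shape[0]).mean(axis=2)
        phi = np.zeros(d)
        for pi, perm in enumerate(perms):
            deltas = np.diff(vals[pi])
            for step, j in enumerate(perm):
                phi[j] += deltas[step]
        phi /= self.n_permutations
        output = float(self.model.predict_proba(x.reshape(1, -1))[0, 1])
        # telescoping guarantees base + sum(phi) == output up to float error
        return AttributionVector(self.feature_names, phi, self.base_value, output)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def local_attribution(model: ProbabilisticClassifier, x: np.ndarray,
                      feature_names: Optional[Sequence[str]] = None,
                      allow_sampling: bool = False,
                      background: Optional[np.ndarray] = None,
                      seed: int = 0) -> AttributionVector:
    """Additive attribution of one visit's SPMS output.

    Tree models get exact path attributions; other kinds require
    ``allow_sampling=True`` plus a background matrix.
    """
    if model.spec.kind in TREE_KINDS:
        return TreeShapleyExplainer(model, feature_names).attribution(x)
    if not allow_sampling:
        raise ValueError(
            f"model kind {model.spec.kind!r} has no exact tree attribution; supported "
            f"exactly: {TREE_KINDS}. Pass allow_sampling=True with a background matrix.")
    if background is None:
        raise ValueError("sampling attribution requires a background matrix")
    return PermutationShapleyExplainer(model, background, seed=seed,
                                       feature_names=feature_names).attribution(x)


def global_importance(model: ProbabilisticClassifier, X: np.ndarray,
                      feature_names: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Mean absolute attribution per feature over a dataset, ranked descending.

    Ties break alphabetically on the feature name.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 1:
        raise ValueError("global importance needs at least one row")
    explainer = TreeShapleyExplainer(model, feature_names)
    phi = explainer.shap_values(X)
    imp = np.abs(phi).mean(axis=0)
    df = pd.DataFrame({"feature": explainer.feature_names, "mean_abs_contribution": imp})
    df = df.sort_values(["mean_abs_contribution", "feature"],
                        ascending=[False, True], kind="mergesort").reset_index(drop=True)
    return df
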