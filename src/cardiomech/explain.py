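"""Shapley feature attribution with an exact enumerator and a sampler.

The score of feature *i* is the Shapley value of the cooperative game
whose characteristic function v maps a feature subset to the mean
cross-validated F1 of a classifier retrained on that subset (v of the
empty set is defined as 0, so efficiency reads: the scores sum to the
full-set F1).  Exact enumeration is feasible up to 15 features; beyond
that a permutation-sampling estimator with per-feature Monte-Carlo
standard errors stands in.
"""

from __future__ import annotations

import dataclasses
import itertools
import math

import numpy as np

from .core_io import FeatureMatrix
from .model import DEFAULT_PARAMS, cross_val_f1, encode_labels

EXACT_LIMIT = 15


@dataclasses.dataclass
class ShapleyResult:
    scores: dict                 # feature -> alpha_i
    value_fn_id: str
    mode: str                    # "exact" | "sampled"
    n_samples: int = 0           # permutations drawn (sampled mode)
    seed: int | None = None
    stderr: dict | None = None   # per-feature MC standard error (sampled)

    def total(self) -> float:
        return float(sum(self.scores.values()))

    def ranking(self) -> list:
        return sorted(self.scores, key=lambda f: abs(self.scores[f]),
                      reverse=True)


class _MemoValue:
    def __init__(self, value_fn):
        self.value_fn = value_fn
        self.cache = {}

    def __call__(self, subset: frozenset):
        if subset not in self.cache:
            try:
                self.cache[subset] = float(self.value_fn(subset))
            except Exception as err:
                raise RuntimeError(
                    f"value function failed on subset {sorted(subset)}") from err
        return self.cache[subset]


def shapley_exact(value_fn, features, value_fn_id: str = "") -> ShapleyResult:
    """Exact Shapley scores by full subset enumeration (memoized v).

    alpha_i = sum over subsets g of F\\{i} of |g|!(|F|-|g|-1)!/|F|! *
    [v(g+i) - v(g)].  Efficiency (sum alpha = v(F) - v(empty)), symmetry
    and the dummy axiom hold exactly.
    """
    features = list(features)
    n = len(features)
    if n > EXACT_LIMIT:
        raise ValueError(f"exact enumeration limited to {EXACT_LIMIT} features")
    v = _MemoValue(value_fn)
    fact = [math.factorial(k) for k in range(n + 1)]
    scores = {f: 0.0 for f in features}
    others = {f: [g for g in features if g != f] for f in features}
    for f in features:
        for size in range(n):
            w = fact[size] * fact[n - size - 1] / fact[n]
            for combo in itertools.combinations(others[f], size):
                g = frozenset(combo)
                scores[f] += w * (v(g | {f}) - v(g))
    return ShapleyResult(scores, value_fn_id, "exact")


def shapley_sampled(value_fn, features, n_permutations: int = 200,
                    seed: int = 0, value_fn_id: str = "") -> ShapleyResult:
    """Permutation-sampling Shapley estimator, deterministic under seed.

    Each random ordering contributes one marginal contribution per
    feature; the estimate is their mean and the reported standard error
    is the sample SD over permutations / sqrt(n_permutations).
    """
    if n_permutations < 50:
        raise ValueError("need at least 50 permutations")
    features = list(features)
    rng = np.random.default_rng(seed)
    v = _MemoValue(value_fn)
    draws = {f: [] for f in features}
    order = np.array(features, dtype=object)
    for _ in range(n_permutations):
        rng.shuffle(order)
        prev = frozenset()
        prev_val = v(prev)
        for f in order:
            cur = prev | {f}
            cur_val = v(cur)
            draws[f].append(cur_val - prev_val)
            prev, prev_val = cur, cur_val
    scores = {f: float(np.mean(d)) for f, d in draws.items()}
    stderr = {f: float(np.std(d, ddof=1) / math.sqrt(len(d)))
              for f, d in draws.items()}
    return ShapleyResult(scores, value_fn_id, "sampled",
                         n_samples=n_permutations, seed=seed, stderr=stderr)


def f1_value_fn(train: FeatureMatrix, family: str = "xgb", folds: int = 10,
                seed: int = 0, params: dict | None = None):
    """Characteristic function: subset -> mean CV F1 retrained on the subset.

    v(empty) = 0 by contract.  The family's hyperparameters are fixed once
    (not re-tuned per subset).
    """
    y = encode_labels(train.labels)
    params = params if params is not None else DEFAULT_PARAMS[family]
    name_to_col = {f: i for i, f in enumerate(train.feature_names)}

    def value(subset) -> float:
        cols = [name_to_col[f] for f in subset]
        if not cols:
            return 0.0
        return cross_val_f1(train.values[:, cols], y, family, params,
                            folds, seed)

    return value


def rank_and_compare(shap: ShapleyResult, importance: dict, k: int) -> dict:
    """Top-k agreement between Shapley scores and a native importance ranking.

    Both rankings are by |score|; returns the two top-k lists, their
    intersection and the overlap fraction |intersection| / k.
    """
    if set(shap.scores) != set(importance):
        raise ValueError("rankings must cover the same feature set")
    k = min(k, len(importance))
    top_shap = shap.ranking()[:k]
    top_imp = sorted(importance, key=lambda f: abs(importance[f]),
                     reverse=True)[:k]
    inter = set(top_shap) & set(top_imp)
    return {"k": k, "top_shapley": top_shap, "top_importance": top_imp,
            "intersection": sorted(inter),
            "overlap_fraction": len(inter) / k if k else np.nan}
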