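"""Classifier training, evaluation and joint (M, N) filter optimization.

The modelling surface follows the Model/Results idiom: an
:class:`ASDetectionModel` is built from a :class:`~cardiomech.core_io.FeatureMatrix`
(or a DataFrame), and ``fit()`` returns an :class:`ASDetectionResults`
carrying the selected hyperparameters, cross-validated and held-out
performance, the confusion table and a ``summary()`` view.

Four classifier families (decision tree, random forest, XGBoost, SVM) sit
behind a uniform build/fit/predict/importance interface; hyperparameters
are selected by mean 10-fold cross-validated F1 over per-family grids that
cover depth/leaf/split/feature limits, split criterion, learning rate
(XGBoost) and class weights.  The train/test split is stratified 80/20 and
— at chunk level — grouped by subject so no subject leaks across the split.

The RMS artifact-filter window M (100-2000 ms) and chunk length N (2-25 s)
are optimized jointly by Bayesian optimization: a Gaussian-process
surrogate (Matern-5/2) with expected-improvement acquisition over the
box, each probe rebuilding the features from scratch on the training
recordings only.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.ensemble import RandomForestClassifier
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.class_weight import compute_sample_weight
from xgboost import XGBClassifier

from .core_io import FeatureMatrix, PipelineConfig
from .pipeline import build_feature_matrices, subject_of

FAMILIES = ("dt", "rf", "xgb", "svm")

M_BOUNDS = (100.0, 2000.0)   # RMS window, ms
N_BOUNDS = (2.0, 25.0)       # chunk length, s


# ---------------------------------------------------------------------------
# uniform classifier interface

def _build_estimator(family: str, params: dict, seed: int):
    params = dict(params)
    weighting = params.pop("class_weight", None)
    if family == "dt":
        est = DecisionTreeClassifier(random_state=seed, class_weight=weighting,
                                     **params)
    elif family == "rf":
        est = RandomForestClassifier(random_state=seed, class_weight=weighting,
                                     n_jobs=1, **params)
    elif family == "svm":
        est = SVC(random_state=seed, class_weight=weighting, **params)
    elif family == "xgb":
        # exact greedy split finding: histogram binning places thresholds at
        # the data extremes of a cluster, which does not generalize at cohort
        # sizes of tens of subjects; exact cuts at midpoints between values
        est = XGBClassifier(random_state=seed, n_jobs=1, tree_method="exact",
                            verbosity=0, **params)
        est._cm_weighting = weighting  # applied as sample weights at fit time
    else:
        raise ValueError(f"unknown family {family!r}")
    return est


def _fit(est, X, y):
    weighting = getattr(est, "_cm_weighting", None)
    if weighting is not None:
        est.fit(X, y, sample_weight=compute_sample_weight(weighting, y))
    else:
        est.fit(X, y)
    return est


def native_importance(est, feature_names) -> dict:
    """Split-gain / impurity / |coef| importance through the uniform surface."""
    if hasattr(est, "feature_importances_"):
        imp = est.feature_importances_
    elif hasattr(est, "coef_"):
        imp = np.abs(np.asarray(est.coef_)).sum(axis=0)
    else:
        raise ValueError("this estimator exposes no native importance "
                         "(e.g. non-linear SVM); use Shapley scores instead")
    return dict(zip(feature_names, np.asarray(imp, float)))


DEFAULT_GRIDS = {
    "dt": {"max_depth": [3, 5, None], "min_samples_leaf": [1, 5],
           "min_samples_split": [2, 10], "max_features": [None, "sqrt"],
           "criterion": ["gini", "entropy"], "class_weight": [None, "balanced"]},
    "rf": {"max_depth": [5, None], "min_samples_leaf": [1, 5],
           "min_samples_split": [2], "max_features": ["sqrt"],
           "criterion": ["gini"], "n_estimators": [50, 100],
           "class_weight": [None, "balanced"]},
    "xgb": {"max_depth": [3, 6], "min_child_weight": [0.5, 1, 5],
            "learning_rate": [0.1, 0.3], "n_estimators": [50],
            "colsample_bytree": [1.0, 0.5], "class_weight": [None, "balanced"]},
    "svm": {"C": [0.1, 1.0, 10.0], "kernel": ["rbf", "linear"],
            "gamma": ["scale"], "class_weight": [None, "balanced"]},
}

#: fixed configurations for contexts that forbid re-tuning (filter
#: optimization objective, Shapley value functions)
DEFAULT_PARAMS = {
    "dt": {"max_depth": 5},
    "rf": {"n_estimators": 60, "max_features": "sqrt"},
    "xgb": {"n_estimators": 40, "max_depth": 3, "learning_rate": 0.3,
            "min_child_weight": 0.5},
    "svm": {"C": 1.0, "kernel": "rbf"},
}


# ---------------------------------------------------------------------------
# labels, metrics

def encode_labels(labels) -> np.ndarray:
    """Binary: AS (any severity) = 1, healthy = 0.  Multi-class: severity order."""
    order = {"healthy": 0, "mild": 1, "moderate": 2, "severe": 3}
    uniq = sorted(set(labels), key=lambda l: order.get(l, 99))
    if len(uniq) <= 2:
        return np.array([0 if l == "healthy" else 1 for l in labels])
    return np.array([order[l] for l in labels])


@dataclasses.dataclass
class Metrics:
    """Precision / recall / accuracy / F1 plus the confusion table."""

    precision: float
    recall: float
    accuracy: float
    f1: float
    confusion: np.ndarray     # C x C, rows = truth
    classes: tuple

    def normalized_confusion(self) -> np.ndarray:
        """Row-normalized (per-truth-class rates) view."""
        c = self.confusion.astype(float)
        rs = c.sum(axis=1, keepdims=True)
        rs[rs == 0] = 1.0
        return c / rs


def f1_from_counts(tp: int, fp: int, fn: int) -> float:
    pr = tp / (tp + fp) if tp + fp else 0.0
    re = tp / (tp + fn) if tp + fn else 0.0
    return 2 * pr * re / (pr + re) if pr + re > 0 else 0.0


def evaluate(y_true, y_pred, classes=None) -> Metrics:
    """Binary metrics with AS as the positive class; macro for multi-class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if classes is None:
        classes = tuple(sorted(set(y_true) | set(y_pred)))
    cm = confusion_matrix(y_true, y_pred, labels=list(classes))
    acc = float(np.trace(cm) / cm.sum())
    if len(classes) == 2:
        tn, fp, fn, tp = cm.ravel()
        pr = tp / (tp + fp) if tp + fp else 0.0
        re = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * pr * re / (pr + re) if pr + re > 0 else 0.0
    else:  # macro average
        prs, res, f1s = [], [], []
        for k in range(len(classes)):
            tp = cm[k, k]
            fp = cm[:, k].sum() - tp
            fn = cm[k, :].sum() - tp
            pr = tp / (tp + fp) if tp + fp else 0.0
            re = tp / (tp + fn) if tp + fn else 0.0
            prs.append(pr)
            res.append(re)
            f1s.append(2 * pr * re / (pr + re) if pr + re > 0 else 0.0)
        pr, re, f1 = map(lambda v: float(np.mean(v)), (prs, res, f1s))
    return Metrics(float(pr), float(re), acc, float(f1), cm, tuple(classes))


# ---------------------------------------------------------------------------
# splits and cross-validation

@dataclasses.dataclass
class SplitSpec:
    level: str
    train_ids: tuple
    test_ids: tuple
    fraction_test: float
    seed: int


def split_dataset(matrix: FeatureMatrix, level: str = "chunk",
                  fraction_test: float = 0.2, seed: int = 0) -> SplitSpec:
    """Stratified 80/20 split; chunk level groups all chunks of a subject.

    The stratification unit is the subject (every chunk of a subject lands
    on the same side), deterministic under ``seed``.
    """
    subjects: dict[str, str] = {}
    for sid, lab in zip(matrix.sample_ids, matrix.labels):
        subjects.setdefault(subject_of(sid), lab)
    rng = np.random.default_rng(seed)
    by_class: dict[str, list] = {}
    for s, lab in subjects.items():
        by_class.setdefault(lab, []).append(s)
    test_subjects = set()
    for lab, subs in sorted(by_class.items()):
        subs = sorted(subs)
        rng.shuffle(subs)
        n_test = max(int(round(fraction_test * len(subs))), 1)
        if n_test >= len(subs):
            raise ValueError(f"class {lab!r} would vanish from the train side")
        test_subjects.update(subs[:n_test])
    train_ids = tuple(s for s in matrix.sample_ids
                      if subject_of(s) not in test_subjects)
    test_ids = tuple(s for s in matrix.sample_ids
                     if subject_of(s) in test_subjects)
    for side, ids in (("train", train_ids), ("test", test_ids)):
        labs = {matrix.labels[matrix.sample_ids.index(i)] for i in ids}
        if labs != set(subjects.values()):
            raise ValueError(f"class missing from the {side} side")
    return SplitSpec(level, train_ids, test_ids, fraction_test, seed)


def cross_val_f1(X, y, family: str, params: dict, folds: int = 10,
                 seed: int = 0) -> float:
    """Mean F1 over stratified k-fold CV; degenerate folds are skipped."""
    X = np.asarray(X, float)
    y = np.asarray(y)
    classes = tuple(sorted(set(y)))
    n_splits = min(folds, int(np.bincount(y).min()), len(y))
    if n_splits < 2:
        return 0.0
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    scores = []
    for tr, te in skf.split(X, y):
        if len(set(y[tr])) < 2:
            warnings.warn("degenerate CV fold skipped (single class)")
            continue
        est = _build_estimator(family, params, seed)
        _fit(est, X[tr], y[tr])
        scores.append(evaluate(y[te], est.predict(X[te]), classes).f1)
    return float(np.mean(scores)) if scores else 0.0


def tune_classifier(train: FeatureMatrix, family: str,
                    grid: dict | None = None, folds: int = 10, seed: int = 0):
    """Exhaustive grid search maximizing mean CV F1; refit on full train.

    Returns ``(fitted_estimator, best_params, best_cv_f1)``.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    grid = grid if grid is not None else DEFAULT_GRIDS[family]
    X = train.values
    y = encode_labels(train.labels)
    keys = sorted(grid)
    best_params, best_f1 = None, -np.inf
    for combo in itertools.product(*(grid[k] for k in keys)):
        params = dict(zip(keys, combo))
        f1 = cross_val_f1(X, y, family, params, folds, seed)
        if f1 > best_f1:
            best_params, best_f1 = params, f1
    est = _fit(_build_estimator(family, best_params, seed), X, y)
    return est, best_params, best_f1


# ---------------------------------------------------------------------------
# Model / Results

class ASDetectionModel:
    """Aortic-stenosis classifier over a cardiomechanical feature matrix.

    Parameters
    ----------
    matrix : FeatureMatrix
        Chunk-level (103 features) or subject-level (133) samples.
    family : {"dt", "rf", "xgb", "svm"}
    level : {"chunk", "subject"}
        Governs the subject-grouped split at chunk level.
    """

    def __init__(self, matrix: FeatureMatrix, family: str = "xgb",
                 level: str = "chunk", folds: int = 10,
                 grid: dict | None = None, fraction_test: float = 0.2,
                 seed: int = 0):
        if family not in FAMILIES:
            raise ValueError(f"unknown family {family!r}")
        self.matrix = matrix
        self.family = family
        self.level = level
        self.folds = folds
        self.grid = grid
        self.fraction_test = fraction_test
        self.seed = seed

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "ASDetectionModel":
        """Build from a DataFrame whose last column is ``label``."""
        return cls(FeatureMatrix.from_dataframe(df), **kwargs)

    def fit(self) -> "ASDetectionResults":
        split = split_dataset(self.matrix, self.level, self.fraction_test,
                              self.seed)
        train = self.matrix.subset(split.train_ids)
        test = self.matrix.subset(split.test_ids)
        est, best_params, cv_f1 = tune_classifier(train, self.family,
                                                  self.grid, self.folds,
                                                  self.seed)
        classes = tuple(sorted(set(encode_labels(self.matrix.labels))))
        y_test = encode_labels_like(test.labels, self.matrix.labels)
        metrics = evaluate(y_test, est.predict(test.values), classes)
        return ASDetectionResults(self, est, split, best_params, cv_f1, metrics)


def encode_labels_like(labels, reference) -> np.ndarray:
    """Encode ``labels`` with the class mapping implied by ``reference``."""
    ref = encode_labels(list(reference) + list(labels))
    return ref[len(list(reference)):]


@dataclasses.dataclass
class ASDetectionResults:
    """Fit artifacts: selected hyperparameters, CV and held-out metrics."""

    model: ASDetectionModel
    estimator: object
    split: SplitSpec
    best_params: dict
    cv_f1: float
    metrics: Metrics

    def feature_importance(self) -> dict:
        return native_importance(self.estimator, self.model.matrix.feature_names)

    def summary(self) -> str:
        m = self.metrics
        lines = [
            "AS detection results",
            "====================",
            f"family:     {self.model.family}",
            f"level:      {self.model.level}",
            f"samples:    {self.model.matrix.n_samples} "
            f"({len(self.split.train_ids)} train / {len(self.split.test_ids)} test)",
            f"features:   {self.model.matrix.n_features}",
            f"CV F1:      {self.cv_f1:.4f}  ({self.model.folds}-fold, train only)",
            "held-out test:",
            f"  precision {m.precision:.4f}  recall {m.recall:.4f}  "
            f"accuracy {m.accuracy:.4f}  F1 {m.f1:.4f}",
            f"best params: {self.best_params}",
            "confusion (rows = truth):",
            str(m.confusion),
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# filter optimization (M, N)

@dataclasses.dataclass
class FilterOptResult:
    M_star: float
    N_star: float
    best_f1: float
    trace: list                      # (M, N, f1) in evaluation order


def make_filter_objective(recordings, family: str = "xgb",
                          config: PipelineConfig | None = None,
                          folds: int = 10, seed: int = 0,
                          overlap: float = 0.0, cache: dict | None = None):
    """Objective F1(M, N): rebuild chunk features from scratch and 10-CV.

    ``recordings`` must be training recordings only — the held-out test
    side never enters the objective.  Probe points with no usable chunks
    score 0.  Results are memoized on (M, N).
    """
    config = config or PipelineConfig()
    recordings = list(recordings)
    cache = cache if cache is not None else {}
    params = DEFAULT_PARAMS[family]

    def objective(M: float, N: float) -> float:
        key = (round(float(M), 6), round(float(N), 6))
        if key in cache:
            return cache[key]
        try:
            mats = build_feature_matrices(recordings, M=M, N=N, overlap=overlap,
                                          config=config, levels=("chunk",))
            mat = mats["chunk"]
            y = encode_labels(mat.labels)
            if len(set(y)) < 2:
                f1 = 0.0
            else:
                f1 = cross_val_f1(mat.values, y, family, params, folds, seed)
        except ValueError:
            f1 = 0.0
        cache[key] = f1
        return f1

    return objective


def _expected_improvement(mu, sigma, best):
    sigma = np.maximum(sigma, 1e-12)
    z = (mu - best) / sigma
    return (mu - best) * sstats.norm.cdf(z) + sigma * sstats.norm.pdf(z)


def optimize_filter_params(recordings, family: str = "xgb",
                           bounds=(M_BOUNDS, N_BOUNDS), budget: int = 40,
                           seed: int = 0, n_initial: int = 8,
                           config: PipelineConfig | None = None,
                           folds: int = 10, objective=None) -> FilterOptResult:
    """Jointly optimize (M, N) with a GP surrogate and EI acquisition.

    Latin-hypercube initialization (``n_initial`` points), then
    ``budget - n_initial`` EI-guided probes; the surrogate is a Matern-5/2
    GP on inputs scaled to the unit square.  Deterministic under ``seed``.
    """
    if budget < max(n_initial, 10):
        raise ValueError("budget must be >= max(n_initial, 10)")
    if objective is None:
        objective = make_filter_objective(recordings, family, config,
                                          folds=folds, seed=seed)
    (m_lo, m_hi), (n_lo, n_hi) = bounds
    rng = np.random.default_rng(seed)
    lhs = sstats.qmc.LatinHypercube(d=2, seed=rng)
    X01 = lhs.random(n_initial)

    def to_box(u):
        return np.column_stack([m_lo + u[:, 0] * (m_hi - m_lo),
                                n_lo + u[:, 1] * (n_hi - n_lo)])

    X = to_box(X01)
    trace = []
    y = []
    for M, N in X:
        f1 = objective(M, N)
        trace.append((float(M), float(N), f1))
        y.append(f1)
    y = list(y)
    X01 = list(X01)
    kernel = (ConstantKernel(1.0, (1e-3, 1e3))
              * Matern(length_scale=[0.3, 0.3], length_scale_bounds=(1e-2, 1e1),
                       nu=2.5)
              + WhiteKernel(1e-4, (1e-8, 1e-1)))
    for _ in range(budget - n_initial):
        gp = GaussianProcessRegressor(kernel=kernel, normalize_y=True,
                                      random_state=seed, alpha=1e-8)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gp.fit(np.asarray(X01), np.asarray(y))
        cand = rng.random((512, 2))
        mu, sigma = gp.predict(cand, return_std=True)
        ei = _expected_improvement(mu, sigma, max(y))
        u = cand[int(np.argmax(ei))][None, :]
        M, N = to_box(u)[0]
        f1 = objective(M, N)
        trace.append((float(M), float(N), f1))
        X01.append(u[0])
        y.append(f1)
    best = int(np.argmax([t[2] for t in trace]))
    M_star, N_star, best_f1 = trace[best]
    return FilterOptResult(M_star, N_star, best_f1, trace)


def plot_sweep(trace, fixed: str = "N", ax=None):
    """Performance-vs-filter-parameter curves from a sweep trace.

    ``fixed="N"`` plots F1 vs M with one line per N value (and vice versa).
    Returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    arr = np.asarray([(m, n, f) for m, n, f in trace], float)
    group_col, x_col, xlabel = ((1, 0, "M (ms)") if fixed == "N"
                                else (0, 1, "N (s)"))
    for g in np.unique(arr[:, group_col]):
        sel = arr[arr[:, group_col] == g]
        sel = sel[np.argsort(sel[:, x_col])]
        ax.plot(sel[:, x_col], sel[:, 2], marker="o",
                label=f"{fixed}={g:g}")
    ax.set_xlabel(xlabel)
    ax.set_ylabel("F1")
    ax.legend(fontsize="small")
    return ax


def sweep_filter_params(recordings, family: str = "xgb",
                        M_list=(100, 500, 1000, 1500, 2000),
                        N_list=(2, 5, 10, 15, 20, 25),
                        config: PipelineConfig | None = None,
                        folds: int = 10, seed: int = 0,
                        objective=None) -> list:
    """Exhaustive grid evaluation of F1(M, N); returns (M, N, f1) triples."""
    if objective is None:
        objective = make_filter_objective(recordings, family, config,
                                          folds=folds, seed=seed)
    trace = []
    for M in M_list:
        for N in N_list:
            if not (M_BOUNDS[0] <= M <= M_BOUNDS[1]
                    and N_BOUNDS[0] <= N <= N_BOUNDS[1]):
                raise ValueError(f"({M}, {N}) outside the optimization box")
            trace.append((float(M), float(N), objective(M, N)))
    return trace
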