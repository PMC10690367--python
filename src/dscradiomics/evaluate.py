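"""Cross-validated SVM classification, metrics and Shapley explanations.

One RBF-kernel support vector classifier is trained per parametric map in
a stratified 5-fold scheme.  Everything data-dependent — feature
selection, z-scoring, SMOTE oversampling, the SVM itself — is fitted on
the training folds only; the test fold is untouched until scoring.

Metrics per fold: sensitivity = TP/(TP+FN), specificity = TN/(FP+TN),
F1 = TP/(TP + 0.5 (FP+FN)), accuracy, and AUROC computed from the ranks
of the decision-function scores (the Mann-Whitney statistic divided by
n+ * n-, ties counted 1/2).

Shapley attributions are computed directly from the coalition definition:
exact enumeration of all 2^p feature coalitions for p <= 12 (features
outside the coalition are replaced by background samples), or a
permutation Monte-Carlo estimate for larger p.  Both satisfy the
efficiency property sum_i phi_i = f(x) - E_background[f].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .selection import SMOTE, SelectionChain

__all__ = [
    "ConfusionCounts",
    "compute_metrics",
    "auroc_from_scores",
    "stratified_kfold",
    "MapClassifier",
    "CVReport",
    "cross_validate_map",
    "cross_validate_all_maps",
    "shapley_exact",
    "shapley_sampled",
    "ShapSummary",
    "shapley_summary",
]

METRIC_NAMES = ("sensitivity", "specificity", "f1", "accuracy", "auroc")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @staticmethod
    def from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        return ConfusionCounts(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        )


def auroc_from_scores(y_true: np.ndarray, scores: np.ndarray) -> float:
    """AUROC via the rank (Mann-Whitney) formulation; ties count 1/2."""
    y_true = np.asarray(y_true).astype(int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(y_true == 1))
    n_neg = int(np.sum(y_true == 0))
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    from scipy.stats import rankdata

    ranks = rankdata(scores)
    u = float(np.sum(ranks[y_true == 1])) - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def compute_metrics(
    counts: ConfusionCounts,
    scores: np.ndarray | None = None,
    y_true: np.ndarray | None = None,
) -> dict[str, float]:
    """Metric suite from confusion counts plus (optionally) ranked scores.

    Undefined ratios (empty positive or negative test set) are NaN."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (fp + tn) if fp + tn else float("nan")
    f1 = tp / (tp + 0.5 * (fp + fn)) if tp + fp + fn else float("nan")
    acc = (tp + tn) / counts.total if counts.total else float("nan")
    out = {"sensitivity": sens, "specificity": spec, "f1": f1, "accuracy": acc}
    if scores is not None and y_true is not None:
        out["auroc"] = auroc_from_scores(y_true, scores)
    return out


def stratified_kfold(labels: np.ndarray, k: int = 5, seed: int = 0) -> np.ndarray:
    """Stratified fold assignment: per-fold class counts differ from the
    proportional share by at most one.  Returns the fold index per sample."""
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2 (no test set otherwise)")
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"every class needs >= k={k} samples")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(labels), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros((len(labels), 1)), labels)):
        assignment[test_idx] = fold
    return assignment


class MapClassifier(ClassifierMixin, BaseEstimator):
    """Per-map pipeline: selection -> z-score -> SMOTE -> SVM-RBF.

    A scikit-learn classifier; everything is fitted in ``fit`` and the
    test data only passes through ``transform`` steps.  SVM defaults are
    C = 1 with the 1/(p * Var) bandwidth heuristic ('scale').
    """

    def __init__(self, variance_threshold: float = 0.5, alpha: float = 0.05,
                 l1_C: float = 0.3, svm_C: float = 1.0, gamma: str | float = "scale",
                 k_neighbors: int = 5, use_smote: bool = True, random_state: int = 0):
        self.variance_threshold = variance_threshold
        self.alpha = alpha
        self.l1_C = l1_C
        self.svm_C = svm_C
        self.gamma = gamma
        self.k_neighbors = k_neighbors
        self.use_smote = use_smote
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y):
        X = pd.DataFrame(X)
        y = np.asarray(y).astype(int)
        if len(np.unique(y)) < 2:
            raise ValueError("training fold contains a single class")
        self.selector_ = SelectionChain(
            self.variance_threshold, self.alpha, self.l1_C
        ).fit(X, y)
        X_sel = self.selector_.transform(X).values
        self.scaler_ = StandardScaler().fit(X_sel)
        X_std = self.scaler_.transform(X_sel)
        if self.use_smote:
            counts = np.bincount(y)
            k = min(self.k_neighbors, int(counts[counts > 0].min()) - 1)
            balanced = SMOTE(k_neighbors=max(1, k),
                             random_state=self.random_state).fit_resample(X_std, y)
            X_fit, y_fit = balanced.X, balanced.y
            self.n_synthetic_ = len(balanced.synthetic_index)
        else:
            X_fit, y_fit = X_std, y
            self.n_synthetic_ = 0
        self.svm_ = SVC(kernel="rbf", C=self.svm_C, gamma=self.gamma)
        self.svm_.fit(X_fit, y_fit)
        self.classes_ = self.svm_.classes_
        return self

    def _prepare(self, X) -> np.ndarray:
        check_is_fitted(self, "svm_")
        return self.scaler_.transform(self.selector_.transform(pd.DataFrame(X)).values)

    def decision_function(self, X) -> np.ndarray:
        return self.svm_.decision_function(self._prepare(X))

    def predict(self, X) -> np.ndarray:
        return self.svm_.predict(self._prepare(X))

    @property
    def selected_features_(self) -> list[str]:
        check_is_fitted(self, "selector_")
        return list(self.selector_.support_names_)


@dataclass
class CVReport:
    """Per-fold and aggregated metrics for one parametric map."""

    map_name: str
    per_fold: pd.DataFrame                  # folds x metrics
    mean: pd.Series
    sd: pd.Series
    fold_assignment: np.ndarray
    selected_features: list[list[str]]
    partial: bool = False
    config: dict = field(default_factory=dict)

    def summary_row(self) -> pd.Series:
        """Mean +/- SD formatted as percentages, one row of the results table."""
        return pd.Series(
            {
                m: f"{100 * self.mean[m]:.1f} ± {100 * self.sd[m]:.1f}"
                for m in METRIC_NAMES
            },
            name=self.map_name,
        )


def cross_validate_map(
    X: pd.DataFrame,
    y: np.ndarray,
    *,
    map_name: str = "map",
    k: int = 5,
    seed: int = 0,
    classifier_kwargs: dict | None = None,
) -> CVReport:
    """Stratified k-fold cross-validation of the per-map pipeline.

    All seeds derive from ``seed``: the fold shuffle uses ``seed`` and the
    SMOTE stream of fold ``i`` uses ``seed + 1000 + i``.  A failed fold is
    recorded and flags the report as partial instead of aborting the run.
    """
    X = pd.DataFrame(X).reset_index(drop=True)
    y = np.asarray(y).astype(int)
    folds = stratified_kfold(y, k=k, seed=seed)
    kwargs = dict(classifier_kwargs or {})
    rows = []
    selected: list[list[str]] = []
    partial = False
    for fold in range(k):
        test = folds == fold
        train = ~test
        try:
            clf = MapClassifier(random_state=seed + 1000 + fold, **kwargs)
            clf.fit(X[train], y[train])
            scores = clf.decision_function(X[test])
            preds = clf.predict(X[test])
        except (ValueError, RuntimeError):
            partial = True
            rows.append({m: np.nan for m in METRIC_NAMES})
            selected.append([])
            continue
        counts = ConfusionCounts.from_predictions(y[test], preds)
        rows.append(compute_metrics(counts, scores, y[test]))
        selected.append(clf.selected_features_)
    per_fold = pd.DataFrame(rows)
    return CVReport(
        map_name=map_name,
        per_fold=per_fold,
        mean=per_fold.mean(),
        sd=per_fold.std(ddof=1),
        fold_assignment=folds,
        selected_features=selected,
        partial=partial,
        config={"k": k, "seed": seed, **kwargs},
    )


def cross_validate_all_maps(
    feature_table: pd.DataFrame,
    *,
    k: int = 5,
    seed: int = 0,
    classifier_kwargs: dict | None = None,
) -> dict[str, CVReport]:
    """One classifier per parametric map (plus the shared shape block).

    ``feature_table`` holds ``map__filter__class__feature`` columns and a
    ``label`` column; the map prefix groups columns per classifier.
    """
    y = feature_table["label"].values
    feature_cols = [c for c in feature_table.columns if c != "label"]
    by_map: dict[str, list[str]] = {}
    shape_cols = [c for c in feature_cols if c.startswith("mask__")]
    for c in feature_cols:
        prefix = c.split("__", 1)[0]
        if prefix == "mask":
            continue
        by_map.setdefault(prefix, []).append(c)
    reports = {}
    for map_name, cols in by_map.items():
        X = feature_table[cols + shape_cols]
        reports[map_name] = cross_validate_map(
            X, y, map_name=map_name, k=k, seed=seed,
            classifier_kwargs=classifier_kwargs,
        )
    return reports


def metrics_table(reports: dict[str, CVReport]) -> pd.DataFrame:
    """Results table: rows = maps, columns = metrics as 'mean +/- sd' %."""
    return pd.DataFrame([r.summary_row() for r in reports.values()])


# ---------------------------------------------------------------------------
# Shapley attributions

def _coalition_value(
    predict, x: np.ndarray, background: np.ndarray, coalition: tuple[int, ...]
) -> float:
    """Expected model output with features in ``coalition`` fixed to x and
    the rest drawn from the background set."""
    z = background.copy()
    if coalition:
        z[:, list(coalition)] = x[list(coalition)]
    return float(np.mean(predict(z)))


def shapley_exact(predict, x: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Exact Shapley values by enumerating all 2^p coalitions (p <= 12).

    phi_i = sum over S not containing i of
            |S|! (p - |S| - 1)! / p!  *  (v(S + i) - v(S))
    with v(S) the background-expectation coalition value.
    """
    x = np.asarray(x, dtype=float)
    background = np.atleast_2d(np.asarray(background, dtype=float))
    p = len(x)
    if p > 12:
        raise ValueError("exact mode enumerates 2^p coalitions; use sampled mode for p > 12")
    values: dict[tuple[int, ...], float] = {}
    for size in range(p + 1):
        for S in combinations(range(p), size):
            values[S] = _coalition_value(predict, x, background, S)
    phi = np.zeros(p)
    for i in range(p):
        others = [j for j in range(p) if j != i]
        for size in range(p):
            w = factorial(size) * factorial(p - size - 1) / factorial(p)
            for S in combinations(others, size):
                S_with = tuple(sorted(S + (i,)))
                phi[i] += w * (values[S_with] - values[S])
    return phi


def shapley_sampled(
    predict,
    x: np.ndarray,
    background: np.ndarray,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> np.ndarray:
    """Permutation Monte-Carlo Shapley estimate.

    Each permutation adds features to the coalition in random order; the
    marginal change in the coalition value when feature i enters is an
    unbiased draw of its Shapley contribution.  Exactly satisfies
    efficiency for every permutation, hence also on average.
    """
    x = np.asarray(x, dtype=float)
    background = np.atleast_2d(np.asarray(background, dtype=float))
    p = len(x)
    rng = np.random.default_rng(seed)
    phi = np.zeros(p)
    base = _coalition_value(predict, x, background, ())
    for _ in range(n_permutations):
        order = rng.permutation(p)
        prev = base
        z = background.copy()
        for i in order:
            z[:, i] = x[i]
            cur = float(np.mean(predict(z)))
            phi[i] += cur - prev
            prev = cur
    return phi / n_permutations


@dataclass
class ShapSummary:
    """Attributions for a set of samples plus the global feature ranking."""

    values: pd.DataFrame            # samples x features
    feature_names: list[str]
    ranking: pd.Series              # mean |phi| per feature, descending
    base_value: float               # mean background prediction
    mode: str


def shapley_summary(
    predict,
    X_explain: np.ndarray,
    background: np.ndarray,
    feature_names: list[str] | None = None,
    mode: str = "auto",
    n_permutations: int = 2_000,
    seed: int = 0,
) -> ShapSummary:
    """Per-sample Shapley attributions and the mean-|phi| feature ranking
    (the ordering of a SHAP summary plot)."""
    X_explain = np.atleast_2d(np.asarray(X_explain, dtype=float))
    background = np.atleast_2d(np.asarray(background, dtype=float))
    p = X_explain.shape[1]
    if mode == "auto":
        mode = "exact" if p <= 12 else "sampled"
    rows = []
    for i, x in enumerate(X_explain):
        if mode == "exact":
            rows.append(shapley_exact(predict, x, background))
        else:
            rows.append(
                shapley_sampled(predict, x, background, n_permutations, seed + i)
            )
    names = feature_names or [f"f{i}" for i in range(p)]
    values = pd.DataFrame(rows, columns=names)
    ranking = values.abs().mean().sort_values(ascending=False)
    base = float(np.mean(predict(background)))
    return ShapSummary(values, list(names), ranking, base, mode)
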