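"""Three-step feature selection and minority oversampling.

The selection chain is: (1) variance threshold (default 0.5) to drop
near-constant features, (2) univariate one-way ANOVA keeping features with
p < alpha (default 0.05), (3) L1-penalized logistic regression at inverse
regularisation C = 0.3, keeping features with nonzero weight.  Survivors
of each step are a subset of the previous step's survivors by
construction.  Features are z-scored (with training statistics only)
before the L1 step because penalized weights are scale-sensitive.

All three selectors are scikit-learn transformers (fit/transform,
get_support) and compose with sklearn pipelines.  SMOTE — synthetic
minority oversampling — is implemented here: each synthetic sample is a
convex combination x + lambda (x_nn - x), lambda ~ U(0,1), of a minority
sample and one of its k nearest minority neighbours; it exposes the
imbalanced-learn style ``fit_resample`` and records the parent indices
and interpolation coefficient of every synthetic sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin, f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted, validate_data

__all__ = [
    "VarianceSelector",
    "AnovaSelector",
    "L1LogisticSelector",
    "SelectionChain",
    "SelectionReport",
    "SMOTE",
    "BalancedSet",
]


class VarianceSelector(SelectorMixin, BaseEstimator):
    """Keep features whose population variance is at least ``threshold``."""

    def __init__(self, threshold: float = 0.5):
        self.threshold = threshold

    def fit(self, X, y=None):
        X = validate_data(self, X, dtype=float)
        self.variances_ = np.var(X, axis=0)
        if not np.any(self.variances_ >= self.threshold):
            raise ValueError(
                "variance threshold removed every feature; rescale inputs "
                "or lower the threshold"
            )
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.variances_ >= self.threshold


class AnovaSelector(SelectorMixin, BaseEstimator):
    """Univariate one-way ANOVA filter: keep features with p < alpha."""

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, X, y):
        X = validate_data(self, X, dtype=float)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("ANOVA filter needs at least two classes")
        self.f_statistic_, self.p_values_ = f_classif(X, y)
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return np.nan_to_num(self.p_values_, nan=1.0) < self.alpha


class L1LogisticSelector(SelectorMixin, BaseEstimator):
    """Select features with nonzero weight in an L1-penalized logistic fit.

    The design matrix is z-scored internally with the statistics of the
    data seen at fit time; the sparse (pure-L1) fit uses the deterministic
    coordinate-descent solver (liblinear) at inverse regularisation ``C``.
    """

    def __init__(self, C: float = 0.3, weight_tol: float = 1e-5,
                 max_iter: int = 10_000, tol: float = 1e-6):
        self.C = C
        self.weight_tol = weight_tol
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y):
        X = validate_data(self, X, dtype=float)
        y = np.asarray(y)
        self.scaler_ = StandardScaler().fit(X)
        model = LogisticRegression(
            l1_ratio=1, C=self.C, solver="liblinear",
            max_iter=self.max_iter, tol=self.tol, random_state=0,
        )
        model.fit(self.scaler_.transform(X), y)
        if model.n_iter_[0] >= self.max_iter:
            raise RuntimeError(
                f"L1 logistic solver hit max_iter={self.max_iter} "
                f"(n_iter={model.n_iter_[0]})"
            )
        self.estimator_ = model
        self.weights_ = model.coef_.ravel()
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return np.abs(self.weights_) > self.weight_tol


@dataclass
class SelectionReport:
    """Per-step survivors and statistics of the full selection chain."""

    variance_survivors: list[str]
    anova_survivors: list[str]
    l1_survivors: list[str]
    f_statistic: pd.Series
    p_values: pd.Series
    l1_weights: pd.Series
    thresholds: dict[str, float] = field(default_factory=dict)

    def nested(self) -> bool:
        return set(self.l1_survivors) <= set(self.anova_survivors) <= set(
            self.variance_survivors
        )


class SelectionChain(BaseEstimator):
    """Variance -> ANOVA -> L1-logistic selection as one transformer.

    Degenerate folds still need a classifier input, so the chain never
    returns an empty feature set: if the ANOVA step retains nothing (the
    expected outcome on null data) it keeps the single best feature by F
    statistic, and if the L1 step zeroes every weight it keeps the ANOVA
    survivors.  Both fallbacks are recorded on the fitted object.
    """

    def __init__(self, variance_threshold: float = 0.5, alpha: float = 0.05,
                 C: float = 0.3):
        self.variance_threshold = variance_threshold
        self.alpha = alpha
        self.C = C

    def fit(self, X: pd.DataFrame, y):
        X = pd.DataFrame(X)
        names = np.asarray(X.columns, dtype=object)
        self.variance_ = VarianceSelector(self.variance_threshold).fit(X.values)
        m1 = self.variance_.get_support()
        self.anova_ = AnovaSelector(self.alpha).fit(X.values[:, m1], y)
        m2 = self.anova_.get_support()
        self.anova_fallback_ = False
        if m2.sum() == 0:
            self.anova_fallback_ = True
            m2 = np.zeros_like(m2)
            m2[int(np.nanargmax(self.anova_.f_statistic_))] = True
        anova_names = names[m1][m2]
        self.l1_fallback_ = False
        if m2.sum() < 2:
            self.support_names_ = list(anova_names)
            self.l1_ = None
            weights = pd.Series(dtype=float)
        else:
            self.l1_ = L1LogisticSelector(self.C).fit(X.values[:, m1][:, m2], y)
            m3 = self.l1_.get_support()
            weights = pd.Series(self.l1_.weights_, index=anova_names)
            if m3.sum() == 0:
                self.l1_fallback_ = True
                self.support_names_ = list(anova_names)
            else:
                self.support_names_ = list(anova_names[m3])
        self.report_ = SelectionReport(
            variance_survivors=list(names[m1]),
            anova_survivors=list(anova_names),
            l1_survivors=list(self.support_names_) if not self.l1_fallback_
            else [n for n in anova_names if abs(weights.get(n, 0.0)) > 1e-5],
            f_statistic=pd.Series(self.anova_.f_statistic_, index=names[m1]),
            p_values=pd.Series(self.anova_.p_values_, index=names[m1]),
            l1_weights=weights,
            thresholds={
                "variance": self.variance_threshold,
                "alpha": self.alpha,
                "C": self.C,
            },
        )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "support_names_")
        return pd.DataFrame(X)[self.support_names_]

    def fit_transform(self, X, y):
        return self.fit(X, y).transform(X)


@dataclass
class BalancedSet:
    """Oversampled data with provenance of every synthetic sample."""

    X: np.ndarray
    y: np.ndarray
    synthetic_index: np.ndarray      # rows of X that are synthetic
    parent_a: np.ndarray             # index into the original minority rows
    parent_b: np.ndarray             # neighbour parent
    lam: np.ndarray                  # interpolation coefficient in [0, 1]


class SMOTE(BaseEstimator):
    """Synthetic minority oversampling by segment interpolation.

    For every synthetic sample a minority point ``x`` and one of its
    ``k_neighbors`` nearest minority neighbours ``x_nn`` (Euclidean
    distance) are drawn, and ``x + lam (x_nn - x)`` with
    ``lam ~ Uniform(0, 1)`` is emitted.  Classes are balanced to
    ``target_ratio`` minority:majority (default 1.0, i.e. full balance).
    """

    def __init__(self, k_neighbors: int = 5, target_ratio: float = 1.0,
                 random_state: int = 0):
        self.k_neighbors = k_neighbors
        self.target_ratio = target_ratio
        self.random_state = random_state

    def fit_resample(self, X, y) -> BalancedSet:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) != 2:
            raise ValueError("SMOTE here supports binary labels")
        minority = classes[np.argmin(counts)]
        majority = classes[np.argmax(counts)]
        n_min, n_maj = counts.min(), counts.max()
        if n_min < 2:
            raise ValueError("minority class needs at least 2 samples")
        k = min(self.k_neighbors, n_min - 1)
        n_needed = max(0, int(round(self.target_ratio * n_maj)) - n_min)

        min_idx = np.nonzero(y == minority)[0]
        X_min = X[min_idx]
        rng = np.random.default_rng(self.random_state)
        if n_needed == 0:
            return BalancedSet(X, y, np.array([], int), np.array([], int),
                               np.array([], int), np.array([]))

        nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min)
        neighbor_idx = nn.kneighbors(X_min, return_distance=False)[:, 1:]

        base = rng.integers(0, n_min, size=n_needed)
        pick = rng.integers(0, k, size=n_needed)
        lam = rng.uniform(0.0, 1.0, size=n_needed)
        nb = neighbor_idx[base, pick]
        synth = X_min[base] + lam[:, None] * (X_min[nb] - X_min[base])

        X_out = np.vstack([X, synth])
        y_out = np.concatenate([y, np.full(n_needed, minority, dtype=y.dtype)])
        synth_rows = np.arange(len(X), len(X) + n_needed)
        return BalancedSet(X_out, y_out, synth_rows, min_idx[base], min_idx[nb], lam)
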