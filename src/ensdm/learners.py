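"""The algorithm registry.

All learners are scikit-learn-style estimators with a uniform contract:
``fit(X, y, sample_weight=None)`` on presence (1) / pseudo-absence (0) labels
and ``predict(X)`` returning finite suitability scores in ``[0, 1]``.

Natively implemented here:

* :class:`SurfaceRangeEnvelope` — a BIOCLIM-style rectangular presence-quantile
  envelope (binary output).
* :class:`MaxentModel` — a penalized presence–background learner in the
  maxent/maxnet family: variables are min–max scaled on background statistics,
  expanded into linear/quadratic/product/hinge/threshold features (the classic
  L/Q/P/H/T classes), and fitted by L1-penalized logistic regression with a
  per-feature-class penalty scaled by the regularization multiplier (RM).
  :func:`tune_maxnet` evaluates an RM × feature-combination grid and selects by
  AICc (delta AICc = 0) with held-out AUC as tie-breaker.

The remaining algorithms (GLM, GAM, CTA, FDA, RF, GBM, ANN, MARS, XGBOOST)
wrap established implementations behind the same contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import SplineTransformer, StandardScaler
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "LearnerSpec",
    "SurfaceRangeEnvelope",
    "FeatureExpander",
    "MaxentModel",
    "TuningResult",
    "aicc",
    "tune_maxnet",
    "make_learner",
    "LEARNER_REGISTRY",
    "FC_CLASSES",
    "DEFAULT_RM_GRID",
    "DEFAULT_FC_GRID",
]

FC_CLASSES = frozenset("LQHPT")
DEFAULT_RM_GRID = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0)
DEFAULT_FC_GRID = ("L", "LQ", "LQH", "H", "LQHP", "LQHPT")

# Per-class base L1 penalties; the effective penalty on feature j is
# RM * BASE[class_j] * sqrt(n_presence), against an unnormalised weighted
# log-likelihood, so the relative shrinkage decays like 1/sqrt(n).
BASE_PENALTY = {"L": 0.05, "Q": 0.05, "P": 0.05, "H": 0.5, "T": 1.0}


def _clip01(p: np.ndarray) -> np.ndarray:
    return np.clip(np.asarray(p, dtype=float), 0.0, 1.0)


class _ProbaMixin:
    """predict() via the wrapped classifier's positive-class probability."""

    def predict(self, X):
        check_is_fitted(self, "clf_")
        X = np.asarray(X, dtype=float)
        if len(self.classes_) == 1:
            return np.full(len(X), float(self.classes_[0]))
        proba = self.clf_.predict_proba(self._transform(X))
        return _clip01(proba[:, list(self.clf_.classes_).index(1)])

    def _transform(self, X):
        return X


# ---------------------------------------------------------------------------
# Surface range envelope
# ---------------------------------------------------------------------------

class SurfaceRangeEnvelope(BaseEstimator):
    """Rectangular presence-quantile envelope (binary suitability).

    A point scores 1 iff every variable lies within the presence
    ``[q, 1 - q]`` quantile interval, else 0.
    """

    def __init__(self, q: float = 0.025):
        self.q = q

    def fit(self, X, y, sample_weight=None):
        if not 0 <= self.q < 0.5:
            raise ValueError("SRE quantile q must lie in [0, 0.5)")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        P = X[y == 1]
        if len(P) < 2:
            raise ValueError("SRE needs at least 2 presence points")
        self.lower_ = np.quantile(P, self.q, axis=0)
        self.upper_ = np.quantile(P, 1.0 - self.q, axis=0)
        self.classes_ = np.array([0, 1])
        return self

    def predict(self, X):
        check_is_fitted(self, "lower_")
        X = np.asarray(X, dtype=float)
        inside = (X >= self.lower_) & (X <= self.upper_)
        return inside.all(axis=1).astype(float)


# ---------------------------------------------------------------------------
# Maxent-style learner
# ---------------------------------------------------------------------------

class FeatureExpander:
    """Expand min–max-scaled variables into L/Q/P/H/T feature columns.

    Scaling statistics come from the background sample and are stored so that
    projections use the identical transform; projected values are clamped to
    the background [min, max] range before expansion.  Variables degenerate on
    the background (max == min) are skipped with a warning.
    """

    def __init__(self, fc: str, n_hinge_knots: int = 50, n_threshold_knots: int = 50):
        fc = fc.upper()
        if not fc or set(fc) - FC_CLASSES:
            raise ValueError(f"FC string must be non-empty over {{L,Q,H,P,T}}, got {fc!r}")
        self.fc = fc
        self.n_hinge_knots = n_hinge_knots
        self.n_threshold_knots = n_threshold_knots

    def fit(self, X_background: np.ndarray) -> "FeatureExpander":
        Xb = np.asarray(X_background, dtype=float)
        self.min_ = Xb.min(axis=0)
        self.max_ = Xb.max(axis=0)
        keep = self.max_ > self.min_
        if not keep.all():
            warnings.warn(f"degenerate variables skipped in feature expansion: "
                          f"{np.nonzero(~keep)[0].tolist()}")
        self.keep_ = keep
        self.hinge_knots_ = np.linspace(0.0, 1.0, self.n_hinge_knots + 2)[1:-1]
        self.threshold_knots_ = np.linspace(0.0, 1.0, self.n_threshold_knots + 2)[1:-1]
        return self

    @property
    def n_vars_(self) -> int:
        return int(self.keep_.sum())

    def n_features(self) -> int:
        p = self.n_vars_
        n = 0
        if "L" in self.fc:
            n += p
        if "Q" in self.fc:
            n += p
        if "H" in self.fc:
            n += 2 * self.n_hinge_knots * p
        if "P" in self.fc:
            n += p * (p - 1) // 2
        if "T" in self.fc:
            n += self.n_threshold_knots * p
        return n

    def transform(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (features, per-feature class labels)."""
        X = np.asarray(X, dtype=float)[:, self.keep_]
        mn, mx = self.min_[self.keep_], self.max_[self.keep_]
        Z = np.clip((X - mn) / (mx - mn), 0.0, 1.0)
        p = Z.shape[1]
        cols: list[np.ndarray] = []
        classes: list[str] = []
        if "L" in self.fc:
            cols.append(Z)
            classes += ["L"] * p
        if "Q" in self.fc:
            cols.append(Z ** 2)
            classes += ["Q"] * p
        if "H" in self.fc:
            for k in self.hinge_knots_:
                cols.append(np.maximum(0.0, (Z - k) / (1.0 - k)))   # forward
                cols.append(np.maximum(0.0, (k - Z) / k))           # reverse
                classes += ["H"] * (2 * p)
        if "P" in self.fc:
            for a, b in combinations(range(p), 2):
                cols.append((Z[:, a] * Z[:, b])[:, None])
                classes.append("P")
        if "T" in self.fc:
            for k in self.threshold_knots_:
                cols.append((Z > k).astype(float))
                classes += ["T"] * p
        F = np.hstack([c if c.ndim == 2 else c[:, None] for c in cols])
        return F, np.asarray(classes)


class MaxentModel(BaseEstimator):
    """Penalized presence–background learner (maxent/maxnet family).

    Fits an L1-penalized logistic presence-vs-background model on the expanded
    feature set; the penalty on each feature is ``rm * base(class) * sqrt(m)``
    with ``m`` the presence count.  ``predict`` returns the plain logistic
    output in [0, 1]; the raw linear score is retained for AICc.

    The per-feature penalty is realised by rescaling feature columns before a
    uniform-penalty L1 fit (the glmnet ``penalty.factor`` device), so large RM
    drives all coefficients to zero and tiny RM approaches the unpenalized fit.
    """

    def __init__(self, fc: str = "LQH", rm: float = 1.0,
                 n_hinge_knots: int = 50, n_threshold_knots: int = 50,
                 max_iter: int = 2000, random_state=None):
        self.fc = fc
        self.rm = rm
        self.n_hinge_knots = n_hinge_knots
        self.n_threshold_knots = n_threshold_knots
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y, sample_weight=None):
        if not self.rm > 0:
            raise ValueError("regularization multiplier rm must be positive")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        m = int((y == 1).sum())
        if m < 10:
            raise ValueError(f"maxent-style fit needs >= 10 presences, got {m}")
        if (y == 0).sum() == 0:
            raise ValueError("maxent-style fit needs background/pseudo-absence points")
        # scaling statistics come from the full model matrix (presences +
        # background), the maxnet convention
        self.expander_ = FeatureExpander(self.fc, self.n_hinge_knots, self.n_threshold_knots).fit(X)
        F, classes = self.expander_.transform(X)
        lam = self.rm * np.array([BASE_PENALTY[c] for c in classes]) * np.sqrt(m)
        # column scaling: uniform-penalty fit on F/lam gives per-feature penalty lam_j
        Fs = F / lam
        clf = LogisticRegression(l1_ratio=1.0, C=1.0, solver="liblinear",
                                 max_iter=self.max_iter, tol=1e-6,
                                 random_state=self.random_state)
        self.converged_ = True
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            clf.fit(Fs, y, sample_weight=sample_weight)
            if any("onverge" in str(w.message) for w in caught):
                self.converged_ = False
        self.coef_ = clf.coef_[0] / lam
        self.intercept_ = float(clf.intercept_[0])
        self.feature_classes_ = classes
        self.classes_ = np.array([0, 1])
        self.n_presence_ = m
        return self

    @property
    def n_nonzero_coefs_(self) -> int:
        check_is_fitted(self, "coef_")
        return int(np.count_nonzero(self.coef_))

    def raw_score(self, X) -> np.ndarray:
        """Linear score on the expanded features (pre-logistic)."""
        check_is_fitted(self, "coef_")
        F, _ = self.expander_.transform(np.asarray(X, dtype=float))
        return F @ self.coef_ + self.intercept_

    def predict(self, X):
        return _clip01(1.0 / (1.0 + np.exp(-self.raw_score(X))))


def aicc(model: MaxentModel, X, y) -> float:
    """Small-sample-corrected AIC of a fitted maxent-style model.

    The predicted suitability is normalised over the presence+background
    sample so the cell probabilities sum to 1 (the Warren–Seifert procedure on
    the suitability surface); ``lnL`` is the summed log-probability of the
    presences; ``k`` the count of nonzero coefficients; ``n`` the presence
    count.  Returns NaN (combination invalid) when ``n - k - 1 <= 0``.

    Normalising the suitability output rather than ``exp(raw score)`` keeps
    the criterion consistent with the Bernoulli fit: the true log
    density-ratio saturates where suitability approaches 1, which an
    exponential-of-linear-score model cannot represent, and normalised
    ``exp(raw)`` would therefore systematically prefer hinge features even
    when the generating response is linear on the logit scale.
    """
    y = np.asarray(y).astype(int)
    n = int((y == 1).sum())
    k = model.n_nonzero_coefs_
    if n - k - 1 <= 0:
        return float("nan")
    p = np.asarray(model.predict(np.asarray(X, dtype=float)), dtype=float)
    total = p.sum()
    if not total > 0:
        return float("nan")
    p = p / total
    lnL = float(np.log(np.maximum(p[y == 1], 1e-300)).sum())
    return 2.0 * k - 2.0 * lnL + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass
class TuningResult:
    """Outcome of the RM × FC grid search."""

    table: pd.DataFrame
    chosen_rm: float
    chosen_fc: str
    reliable: list[tuple[float, str]] = field(default_factory=list)  # delta AICc < 2

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def tune_maxnet(
    X,
    y,
    sample_weight=None,
    rm_grid=DEFAULT_RM_GRID,
    fc_grid=DEFAULT_FC_GRID,
    n_hinge_knots: int = 50,
    n_threshold_knots: int = 50,
    seed: int = 0,
    test_frac: float = 0.25,
) -> TuningResult:
    """Evaluate every RM × FC combination; select by AICc.

    Per combination the model is fitted twice: on a seeded stratified 75/25
    split for held-out AUC, and on the full sample for AICc.  The chosen
    combination has delta AICc = 0; ties break by higher AUC, then smaller RM,
    then shorter FC string; combinations with undefined AICc are recorded as
    invalid.  The delta AICc < 2 set is reported as "reliable".
    """
    from .metrics import auc as auc_score

    rm_grid = list(rm_grid)
    fc_grid = list(fc_grid)
    if not rm_grid or not fc_grid:
        raise ValueError("tuning grids must be non-empty")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    w = None if sample_weight is None else np.asarray(sample_weight, dtype=float)

    rng = np.random.default_rng(seed)
    test = np.zeros(len(y), dtype=bool)
    for cls in (0, 1):
        idx = np.nonzero(y == cls)[0]
        n_test = max(1, int(round(test_frac * len(idx))))
        test[rng.permutation(idx)[:n_test]] = True
    train = ~test

    rows = []
    for rm in rm_grid:
        for fc in fc_grid:
            rec = {"rm": rm, "fc": fc, "aicc": np.nan, "auc": np.nan,
                   "n_nonzero": 0, "valid": False}
            try:
                m_cv = MaxentModel(fc=fc, rm=rm, n_hinge_knots=n_hinge_knots,
                                   n_threshold_knots=n_threshold_knots, random_state=0)
                m_cv.fit(X[train], y[train],
                         sample_weight=None if w is None else w[train])
                rec["auc"] = auc_score(y[test], m_cv.predict(X[test]))
                m_full = MaxentModel(fc=fc, rm=rm, n_hinge_knots=n_hinge_knots,
                                     n_threshold_knots=n_threshold_knots, random_state=0)
                m_full.fit(X, y, sample_weight=w)
                rec["n_nonzero"] = m_full.n_nonzero_coefs_
                a = aicc(m_full, X, y)
                if np.isfinite(a):
                    rec["aicc"] = a
                    rec["valid"] = True
            except Exception as exc:  # noqa: BLE001 — failed combination stays invalid
                rec["error"] = str(exc)
            rows.append(rec)
    table = pd.DataFrame(rows)
    valid = table[table["valid"]]
    if valid.empty:
        raise RuntimeError("maxent tuning: every RM x FC combination was invalid")
    table["delta_aicc"] = table["aicc"] - valid["aicc"].min()
    best = table[table["delta_aicc"] == 0].sort_values(
        by=["auc", "rm", "fc"],
        ascending=[False, True, True],
        key=lambda s: s.str.len() if s.name == "fc" else s,
    ).iloc[0]
    reliable = [
        (float(r.rm), str(r.fc))
        for r in table[table["delta_aicc"] < 2].itertuples()
    ]
    cols = ["rm", "fc", "aicc", "delta_aicc", "auc", "n_nonzero", "valid"]
    return TuningResult(table[cols + [c for c in table.columns if c not in cols]],
                        float(best["rm"]), str(best["fc"]), reliable)


# ---------------------------------------------------------------------------
# Standard learners
# ---------------------------------------------------------------------------

class GLMLearner(_ProbaMixin, BaseEstimator):
    """Unpenalized logistic regression on a quadratic formula.

    Each predictor enters linearly and squared (standardized first), the
    biomod2 default GLM formula; ``formula="linear"`` restricts to linear
    terms only.
    """

    def __init__(self, formula: str = "quadratic", max_iter: int = 1000,
                 random_state=None):
        self.formula = formula
        self.max_iter = max_iter
        self.random_state = random_state

    def _design(self, X):
        Z = (np.asarray(X, dtype=float) - self.mu_) / self.sd_
        if self.formula == "quadratic":
            return np.hstack([Z, Z ** 2])
        return Z

    def fit(self, X, y, sample_weight=None):
        if self.formula not in ("linear", "quadratic"):
            raise ValueError(f"unknown GLM formula {self.formula!r}")
        X = np.asarray(X, dtype=float)
        self.mu_ = X.mean(axis=0)
        self.sd_ = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
        self.clf_ = LogisticRegression(C=np.inf, max_iter=self.max_iter)
        self.clf_.fit(self._design(X), y, sample_weight=sample_weight)
        self.classes_ = self.clf_.classes_
        self.coef_ = self.clf_.coef_[0]
        return self

    def _transform(self, X):
        return self._design(X)


class GAMLearner(_ProbaMixin, BaseEstimator):
    """Penalized spline-basis logistic regression (additive model)."""

    def __init__(self, n_knots: int = 5, degree: int = 3, C: float = 1.0,
                 max_iter: int = 1000, random_state=None):
        self.n_knots = n_knots
        self.degree = degree
        self.C = C
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y, sample_weight=None):
        self.spline_ = SplineTransformer(n_knots=self.n_knots, degree=self.degree)
        F = self.spline_.fit_transform(np.asarray(X, dtype=float))
        self.clf_ = LogisticRegression(C=self.C, max_iter=self.max_iter)
        self.clf_.fit(F, y, sample_weight=sample_weight)
        self.classes_ = self.clf_.classes_
        return self

    def _transform(self, X):
        return self.spline_.transform(X)


class CTALearner(_ProbaMixin, BaseEstimator):
    """Classification tree."""

    def __init__(self, max_depth=None, min_samples_leaf: int = 5, random_state=None):
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf
        self.random_state = random_state

    def fit(self, X, y, sample_weight=None):
        self.clf_ = DecisionTreeClassifier(max_depth=self.max_depth,
                                           min_samples_leaf=self.min_samples_leaf,
                                           random_state=self.random_state)
        self.clf_.fit(X, y, sample_weight=sample_weight)
        self.classes_ = self.clf_.classes_
        return self


class RFLearner(_ProbaMixin, BaseEstimator):
    """Random forest."""

    def __init__(self, n_estimators: int = 200, min_samples_leaf: int = 1, random_state=None):
        self.n_estimators = n_estimators
        self.min_samples_leaf = min_samples_leaf
        self.random_state = random_state

    def fit(self, X, y, sample_weight=None):
        self.clf_ = RandomForestClassifier(n_estimators=self.n_estimators,
                                           min_samples_leaf=self.min_samples_leaf,
                                           random_state=self.random_state)
        self.clf_.fit(X, y, sample_weight=sample_weight)
        self.classes_ = self.clf_.classes_
        return self


class GBMLearner(_ProbaMixin, BaseEstimator):
    """Gradient-boosted trees."""

    def __init__(self, n_estimators: int = 100, learning_rate: float = 0.1,
                 max_depth: int = 3, random_state=None):
        self.n_estimators = n_estimators
        self.learning_rate = learning_rate
        self.max_depth = max_depth
        self.random_state = random_state

    def fit(self, X, y, sample_weight=None):
        self.clf_ = GradientBoostingClassifier(n_estimators=self.n_estimators,
                                               learning_rate=self.learning_rate,
                                               max_depth=self.max_depth,
                                               random_state=self.random_state)
        self.clf_.fit(X, y, sample_weight=sample_weight)
        self.classes_ = self.clf_.classes_
        return self


class ANNLearner(_ProbaMixin, BaseEstimator):
    """Feed-forward neural network (inputs standardized; weights not supported)."""

    def __init__(self, hidden_layer_sizes=(8,), max_iter: int = 500, random_state=None):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y, sample_weight=None):
        self.scaler_ = StandardScaler().fit(X)
        self.clf_ = MLPClassifier(hidden_layer_sizes=self.hidden_layer_sizes,
                                  max_iter=self.max_iter, random_state=self.random_state)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.clf_.fit(self.scaler_.transform(X), y)
        self.classes_ = self.clf_.classes_
        return self

    def _transform(self, X):
        return self.scaler_.transform(X)


class XGBLearner(_ProbaMixin, BaseEstimator):
    """Extreme gradient boosting."""

    def __init__(self, n_estimators: int = 100, learning_rate: float = 0.1,
                 max_depth: int = 3, random_state=None):
        self.n_estimators = n_estimators
        self.learning_rate = learning_rate
        self.max_depth = max_depth
        self.random_state = random_state

    def fit(self, X, y, sample_weight=None):
        from xgboost import XGBClassifier

        self.clf_ = XGBClassifier(n_estimators=self.n_estimators,
                                  learning_rate=self.learning_rate,
                                  max_depth=self.max_depth,
                                  random_state=self.random_state or 0,
                                  verbosity=0)
        self.clf_.fit(np.asarray(X, dtype=float), y, sample_weight=sample_weight)
        self.classes_ = self.clf_.classes_
        return self


class _HingeBasis:
    """Per-variable forward/reverse hinge features at presence-range knots."""

    def __init__(self, n_knots: int = 10):
        self.n_knots = n_knots

    def fit(self, X):
        X = np.asarray(X, dtype=float)
        self.min_ = X.min(axis=0)
        self.max_ = np.maximum(X.max(axis=0), self.min_ + 1e-12)
        self.knots_ = np.linspace(0.0, 1.0, self.n_knots + 2)[1:-1]
        return self

    def transform(self, X):
        Z = np.clip((np.asarray(X, dtype=float) - self.min_) / (self.max_ - self.min_), 0.0, 1.0)
        cols = [Z]
        for k in self.knots_:
            cols.append(np.maximum(0.0, Z - k))
            cols.append(np.maximum(0.0, k - Z))
        return np.hstack(cols)


class MARSLearner(_ProbaMixin, BaseEstimator):
    """Adaptive piecewise-linear (hinge-basis) additive model with L1 selection."""

    def __init__(self, n_knots: int = 10, C: float = 1.0, max_iter: int = 2000,
                 random_state=None):
        self.n_knots = n_knots
        self.C = C
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y, sample_weight=None):
        self.basis_ = _HingeBasis(self.n_knots).fit(X)
        self.clf_ = LogisticRegression(l1_ratio=1.0, C=self.C, solver="liblinear",
                                       max_iter=self.max_iter,
                                       random_state=self.random_state)
        self.clf_.fit(self.basis_.transform(X), y, sample_weight=sample_weight)
        self.classes_ = self.clf_.classes_
        return self

    def _transform(self, X):
        return self.basis_.transform(X)


class FDALearner(_ProbaMixin, BaseEstimator):
    """Flexible discriminant analysis: LDA on a hinge feature basis (weights not supported)."""

    def __init__(self, n_knots: int = 5, random_state=None):
        self.n_knots = n_knots
        self.random_state = random_state

    def fit(self, X, y, sample_weight=None):
        self.basis_ = _HingeBasis(self.n_knots).fit(X)
        self.clf_ = LinearDiscriminantAnalysis()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.clf_.fit(self.basis_.transform(X), y)
        self.classes_ = self.clf_.classes_
        return self

    def _transform(self, X):
        return self.basis_.transform(X)


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

LEARNER_REGISTRY: dict[str, type] = {
    "ANN": ANNLearner,
    "CTA": CTALearner,
    "FDA": FDALearner,
    "GAM": GAMLearner,
    "GBM": GBMLearner,
    "GLM": GLMLearner,
    "MAXENT": MaxentModel,
    "MARS": MARSLearner,
    "MAXNET": MaxentModel,
    "RF": RFLearner,
    "XGBOOST": XGBLearner,
    "SRE": SurfaceRangeEnvelope,
}


@dataclass(frozen=True)
class LearnerSpec:
    """A registry name plus hyperparameter overrides."""

    name: str
    hyperparams: tuple = ()

    def __post_init__(self) -> None:
        if self.name not in LEARNER_REGISTRY:
            raise ValueError(f"unknown learner {self.name!r}; "
                             f"known: {sorted(LEARNER_REGISTRY)}")

    @classmethod
    def of(cls, name: str, **hyperparams) -> "LearnerSpec":
        return cls(name, tuple(sorted(hyperparams.items())))


def make_learner(spec: LearnerSpec, random_state=None):
    """Instantiate a registry learner; unknown hyperparameters are rejected."""
    cls = LEARNER_REGISTRY[spec.name]
    kwargs = dict(spec.hyperparams)
    est = cls(**kwargs)
    if random_state is not None and "random_state" in est.get_params():
        est.set_params(random_state=random_state)
    return est
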