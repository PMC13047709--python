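"""Multivariate environmental similarity surface (MESS) and most-dissimilar
variable (MoD).

Per variable j, with ``f`` the percentage of reference values strictly below
the query value ``p``:

* ``f = 0``   → S = 100·(p − min)/(max − min)   (negative below the range)
* ``0 < f ≤ 50`` → S = 2f
* ``50 ≤ f < 100`` → S = 2(100 − f)
* ``f = 100`` → S = 100·(max − p)/(max − min)   (negative above the range)

The cell score is the minimum over variables; S = 100 only when every variable
sits exactly at its reference median, and S ≤ 0 iff at least one variable lies
outside its reference range.  The MoD is the variable attaining the minimum
(smallest index on ties).

:class:`Mess` follows the scikit-learn fit/transform idiom: ``fit`` on the
reference predictor matrix (the model training points), ``transform`` a
projection stack into S and MoD grids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .grid import EnvStack, GridSpec

__all__ = ["mess_point", "mess_scores", "Mess", "MessResult"]


def mess_point(reference_values: np.ndarray, p: float) -> float:
    """Similarity of a single value against one variable's reference sample."""
    ref = np.sort(np.asarray(reference_values, dtype=float))
    if ref[-1] == ref[0]:
        raise ValueError("degenerate reference: all values equal")
    return float(_piecewise(ref, np.array([p]))[0])


def _piecewise(sorted_ref: np.ndarray, p: np.ndarray) -> np.ndarray:
    n = len(sorted_ref)
    mn, mx = sorted_ref[0], sorted_ref[-1]
    f = 100.0 * np.searchsorted(sorted_ref, p, side="left") / n
    S = np.where(f <= 50.0, 2.0 * f, 2.0 * (100.0 - f))
    S = np.where(f == 0.0, 100.0 * (p - mn) / (mx - mn), S)
    S = np.where(f == 100.0, 100.0 * (mx - p) / (mx - mn), S)
    return S


def mess_scores(reference: np.ndarray, query: np.ndarray) -> np.ndarray:
    """Per-variable similarity matrix (n_query, n_vars)."""
    reference = np.asarray(reference, dtype=float)
    query = np.asarray(query, dtype=float)
    if reference.ndim != 2 or query.ndim != 2 or reference.shape[1] != query.shape[1]:
        raise ValueError("reference and query must be 2-D with equal column counts")
    out = np.empty_like(query)
    for j in range(reference.shape[1]):
        ref = np.sort(reference[:, j])
        if ref[-1] == ref[0]:
            raise ValueError(f"degenerate reference variable at column {j}")
        out[:, j] = _piecewise(ref, query[:, j])
    return out


@dataclass
class MessResult:
    spec: GridSpec
    S: np.ndarray            # per-cell minimum similarity; NaN on masked cells
    mod_index: np.ndarray    # argmin variable index; -1 on masked cells
    var_names: list[str]
    per_variable: dict[str, np.ndarray] | None = None

    def extrapolated_fraction(self) -> float:
        """Fraction of valid cells with S <= 0 (beyond the reference range)."""
        valid = np.isfinite(self.S)
        return float((self.S[valid] <= 0).mean()) if valid.any() else 0.0

    def anomaly_classes(self) -> np.ndarray:
        """Reporting bins: 2 extreme (S < 0), 1 anomalous (0 <= S < 10), 0 similar."""
        out = np.full(self.S.shape, -1, dtype=int)
        valid = np.isfinite(self.S)
        out[valid] = 0
        out[valid & (self.S < 10)] = 1
        out[valid & (self.S < 0)] = 2
        return out


class Mess(BaseEstimator):
    """MESS/MoD estimator.

    Parameters
    ----------
    keep_per_variable : bool
        If True, :meth:`transform` also returns the per-variable similarity
        grids.
    """

    def __init__(self, keep_per_variable: bool = False):
        self.keep_per_variable = keep_per_variable

    def fit(self, reference: np.ndarray, var_names: list[str]):
        reference = np.asarray(reference, dtype=float)
        var_names = list(var_names)
        if reference.shape[1] != len(var_names):
            raise ValueError("var_names length must match reference columns")
        keep, sorted_refs, kept_names = [], [], []
        for j, nm in enumerate(var_names):
            ref = np.sort(reference[:, j])
            if len(ref) < 2 or ref[-1] == ref[0]:
                warnings.warn(f"MESS: degenerate reference variable {nm!r} skipped")
                continue
            keep.append(j)
            sorted_refs.append(ref)
            kept_names.append(nm)
        if not keep:
            raise ValueError("MESS: no usable reference variables")
        self.var_names_ = kept_names
        self.sorted_refs_ = sorted_refs
        return self

    def score_points(self, query: np.ndarray) -> np.ndarray:
        """Per-variable similarity (n_query, n_kept_vars)."""
        check_is_fitted(self, "sorted_refs_")
        query = np.asarray(query, dtype=float)
        out = np.empty((len(query), len(self.sorted_refs_)))
        for j, ref in enumerate(self.sorted_refs_):
            out[:, j] = _piecewise(ref, query[:, j])
        return out

    def transform(self, projection: EnvStack) -> MessResult:
        check_is_fitted(self, "sorted_refs_")
        missing = [nm for nm in self.var_names_ if nm not in projection]
        if missing:
            raise KeyError(f"projection stack lacks MESS variables: {missing}")
        Q = projection.values_matrix(self.var_names_)
        Sj = self.score_points(Q)
        spec = projection.spec
        S = np.full((spec.n_rows, spec.n_cols), np.nan)
        mod = np.full((spec.n_rows, spec.n_cols), -1, dtype=int)
        S[projection.mask] = Sj.min(axis=1)
        mod[projection.mask] = Sj.argmin(axis=1)   # argmin -> smallest index on ties
        per = None
        if self.keep_per_variable:
            per = {}
            for j, nm in enumerate(self.var_names_):
                g = np.full((spec.n_rows, spec.n_cols), np.nan)
                g[projection.mask] = Sj[:, j]
                per[nm] = g
        return MessResult(spec, S, mod, list(self.var_names_), per)
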