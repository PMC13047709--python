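"""Predictor screening: permutation contribution rates and Pearson correlation.

Two rules, applied greedily in descending contribution order:

* a variable whose contribution rate falls below ``c_min_percent`` (default
  0.5 %) is dropped — the comparison is strict (``c < c_min``), so a variable
  sitting exactly at the boundary is retained;
* of any pair with ``|r| >= r_max`` (default 0.8) only the variable with the
  higher contribution is retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import EnvStack

__all__ = [
    "ImportanceTable",
    "CorrelationMatrix",
    "permutation_importance",
    "pearson_matrix",
    "screen",
    "ScreeningResult",
]


@dataclass
class ImportanceTable:
    """Per-variable contribution percentages.

    Entries must be non-negative; tables produced by
    :func:`permutation_importance` additionally sum to 100 (checked when
    ``normalized`` is set).
    """

    entries: dict[str, float]
    n_shuffles: int = 5
    seed: int = 0
    normalized: bool = False

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.entries.values()):
            raise ValueError("contribution percentages must be non-negative")
        total = sum(self.entries.values())
        if self.normalized and total > 0 and abs(total - 100.0) > 1e-6:
            raise ValueError(f"contribution percentages sum to {total}, expected 100")


@dataclass
class CorrelationMatrix:
    variables: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        p = len(self.variables)
        if self.r.shape != (p, p):
            raise ValueError("correlation matrix shape does not match variables")

    def get(self, a: str, b: str) -> float:
        ia, ib = self.variables.index(a), self.variables.index(b)
        return float(self.r[ia, ib])


def permutation_importance(model, X: np.ndarray, var_names, n_shuffles: int = 5, seed: int = 0) -> ImportanceTable:
    """Prediction-permutation contribution rates.

    For each variable j, importance is the mean over shuffles of
    ``1 − pearson(pred_reference, pred_with_column_j_permuted)``; negatives are
    clipped to 0 and the vector is normalised to percentages.  A model that
    ignores a variable gets exactly 0 %.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("permutation importance needs at least 3 rows")
    var_names = list(var_names)
    rng = np.random.default_rng(seed)
    ref = np.asarray(model.predict(X), dtype=float)
    if np.std(ref) == 0:
        warnings.warn("reference predictions are constant; all importances set to 0")
        return ImportanceTable({v: 0.0 for v in var_names}, n_shuffles, seed, normalized=True)
    raw = np.zeros(len(var_names))
    for j in range(X.shape[1]):
        vals = []
        for _ in range(n_shuffles):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            pred = np.asarray(model.predict(Xp), dtype=float)
            if np.std(pred) == 0:
                r = 0.0
            else:
                r = float(np.corrcoef(ref, pred)[0, 1])
            vals.append(1.0 - r)
        raw[j] = max(0.0, float(np.mean(vals)))
    total = raw.sum()
    if total == 0:
        pct = raw
    else:
        pct = 100.0 * raw / total
    return ImportanceTable(dict(zip(var_names, pct)), n_shuffles, seed, normalized=True)


def pearson_matrix(data: EnvStack | np.ndarray, var_names=None) -> CorrelationMatrix:
    """Pairwise Pearson correlations over jointly valid entries.

    Accepts either a stack (correlations over all valid cells, the ENMTools
    convention) or a plain (n, p) matrix.  A zero-variance variable yields
    correlation 0 against everything (with a warning), diagonal excepted.
    """
    if isinstance(data, EnvStack):
        names = list(var_names) if var_names is not None else data.layer_names
        M = data.values_matrix(names)
    else:
        M = np.asarray(data, dtype=float)
        names = list(var_names) if var_names is not None else [f"var{j}" for j in range(M.shape[1])]
    if M.shape[0] < 3:
        raise ValueError("need at least 3 rows/cells for correlation")
    p = M.shape[1]
    r = np.eye(p)
    sd = np.array([np.nanstd(M[:, j]) for j in range(p)])
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(f"zero-variance variables (correlations reported as 0): "
                      f"{[names[j] for j in np.nonzero(degenerate)[0]]}")
    for i in range(p):
        for j in range(i + 1, p):
            both = np.isfinite(M[:, i]) & np.isfinite(M[:, j])
            if degenerate[i] or degenerate[j] or both.sum() < 3:
                val = 0.0
            else:
                val = float(np.corrcoef(M[both, i], M[both, j])[0, 1])
            r[i, j] = r[j, i] = val
    return CorrelationMatrix(names, r)


@dataclass
class ScreeningResult:
    retained: list[str]
    log: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_csv(self, path) -> None:
        self.log.to_csv(path, index=False)


def screen(
    importances: ImportanceTable,
    cors: CorrelationMatrix,
    c_min_percent: float = 0.5,
    r_max: float = 0.8,
) -> ScreeningResult:
    """Greedy two-rule screening.

    Variables are visited in descending contribution order (ties broken
    alphabetically).  A variable is dropped if its contribution is strictly
    below ``c_min_percent``, or if it correlates at ``|r| >= r_max`` with any
    already-retained variable; the log records each decision.
    """
    missing = set(importances.entries) ^ set(cors.variables)
    if missing:
        raise ValueError(f"importances and correlations cover different variables: {sorted(missing)}")
    order = sorted(importances.entries, key=lambda v: (-importances.entries[v], v))
    retained: list[str] = []
    rows = []
    for v in order:
        c = importances.entries[v]
        if c < c_min_percent:
            rows.append((v, c, False, "contribution", ""))
            continue
        partner = next((u for u in retained if abs(cors.get(v, u)) >= r_max), None)
        if partner is not None:
            rows.append((v, c, False, "correlation", partner))
            continue
        if abs(c - c_min_percent) < 1e-12:
            # boundary case kept (rule is strict-below); flagged in the log
            rows.append((v, c, True, "boundary", ""))
        else:
            rows.append((v, c, True, "", ""))
        retained.append(v)
    log = pd.DataFrame(rows, columns=["variable", "contribution_pct", "retained", "drop_reason", "partner"])
    return ScreeningResult(retained, log)
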