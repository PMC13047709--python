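"""Member gating and the TSS-weighted ensemble.

Algorithms whose mean test AUC exceeds 0.90 **and** mean test TSS exceeds 0.80
(strict inequalities) contribute all their ok runs as ensemble members; the
ensemble prediction is the TSS-proportional weighted average of member
suitabilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import EnvStack
from .metrics import algorithm_summary, auc, tss
from .occurrences import ModelingDataset

__all__ = ["EnsembleError", "select_members", "EnsembleModel",
           "evaluate_ensemble", "response_curve", "project"]


class EnsembleError(RuntimeError):
    pass


def select_members(
    member_table: pd.DataFrame,
    auc_min: float = 0.90,
    tss_min: float = 0.80,
    level: str = "algorithm",
) -> pd.DataFrame:
    """Gate members by AUC/TSS.

    ``level="algorithm"``: an algorithm passes iff its mean AUC > auc_min and
    mean TSS > tss_min; all its ok runs become members.  ``level="run"``:
    the gate applies per run.
    """
    if member_table.empty:
        raise ValueError("empty member table")
    ok = member_table[member_table["status"] == "ok"]
    if level == "algorithm":
        summ = algorithm_summary(member_table)
        passing = summ[(summ["mean_auc"] > auc_min) & (summ["mean_tss"] > tss_min)]["algorithm"]
        selected = ok[ok["algorithm"].isin(set(passing))]
    elif level == "run":
        selected = ok[(ok["auc"] > auc_min) & (ok["tss"] > tss_min)]
    else:
        raise ValueError(f"unknown gate level {level!r}")
    if selected.empty:
        raise EnsembleError(
            f"no members pass the gate (AUC > {auc_min}, TSS > {tss_min}); "
            "consider relaxing the thresholds"
        )
    return selected.copy()


@dataclass
class EnsembleModel:
    """TSS-weighted committee of gate-passing member models.

    ``weights`` are proportional to each member's test TSS, renormalized to
    sum to 1.  A member whose prediction fails at scoring time is dropped with
    a warning and the remaining weights renormalized.
    """

    members: list            # fitted learners
    member_keys: list        # (algorithm, pa_set, rep) per member
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    @classmethod
    def from_selection(cls, selected: pd.DataFrame, models: dict) -> "EnsembleModel":
        members, keys, tss_w = [], [], []
        for r in selected.itertuples():
            key = (r.algorithm, r.pa_set, r.rep)
            if key not in models:
                continue
            members.append(models[key])
            keys.append(key)
            tss_w.append(max(float(r.tss), 0.0))
        if not members:
            raise EnsembleError("no fitted models available for the selected members")
        w = np.asarray(tss_w, dtype=float)
        if w.sum() == 0:
            w = np.ones(len(members))
        return cls(members, keys, w / w.sum())

    def __post_init__(self) -> None:
        if not self.members:
            raise EnsembleError("ensemble needs at least one member")
        if self.weights is None:
            self.weights = np.full(len(self.members), 1.0 / len(self.members))
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.isclose(self.weights.sum(), 1.0):
            self.weights = self.weights / self.weights.sum()

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        preds, w = [], []
        for model, key, wi in zip(self.members, self.member_keys, self.weights):
            try:
                preds.append(np.asarray(model.predict(X), dtype=float))
                w.append(wi)
            except Exception as exc:  # noqa: BLE001
                warnings.warn(f"ensemble member {key} failed to predict and was dropped: {exc}")
        if not preds:
            raise EnsembleError("every ensemble member failed to predict")
        w = np.asarray(w)
        w = w / w.sum()
        out = np.tensordot(w, np.vstack(preds), axes=1)
        return np.clip(out, 0.0, 1.0)


def evaluate_ensemble(em: EnsembleModel, datasets: list[ModelingDataset]) -> tuple[float, float]:
    """Mean test-fold AUC and TSS of the ensemble across all repetitions."""
    aucs, tsss = [], []
    for ds in datasets:
        for rep in range(ds.n_reps):
            _, te = ds.fold(rep)
            pred = em.predict(ds.X[te])
            aucs.append(auc(ds.y[te], pred))
            tsss.append(tss(ds.y[te], pred)[0])
    return float(np.mean(aucs)), float(np.mean(tsss))


def response_curve(
    em: EnsembleModel,
    stack: EnvStack,
    variable: str,
    var_names: list[str] | None = None,
    n_points: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluation-strip response curve for one variable.

    The target variable sweeps its observed valid-cell range over ``n_points``
    while every other variable is held at its median over valid cells.
    """
    var_names = var_names if var_names is not None else stack.layer_names
    if variable not in var_names:
        raise KeyError(f"variable {variable!r} not among predictors {var_names}")
    M = stack.values_matrix(var_names)
    j = var_names.index(variable)
    med = np.nanmedian(M, axis=0)
    grid = np.linspace(np.nanmin(M[:, j]), np.nanmax(M[:, j]), n_points)
    X = np.tile(med, (n_points, 1))
    X[:, j] = grid
    return grid, em.predict(X)


def project(em: EnsembleModel, stack: EnvStack, var_names: list[str] | None = None) -> np.ndarray:
    """Score every valid cell of a scenario stack; returns a suitability grid
    (NaN on masked cells)."""
    var_names = var_names if var_names is not None else stack.layer_names
    M = stack.values_matrix(var_names)
    P = np.full((stack.spec.n_rows, stack.spec.n_cols), np.nan)
    P[stack.mask] = em.predict(M)
    return P
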