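"""Model evaluation: rank-based AUC, threshold-maximized TSS, and the
algorithm × pseudo-absence-set × repetition protocol producing the member table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .learners import LearnerSpec, make_learner
from .occurrences import ModelingDataset

__all__ = ["EvalScores", "auc", "tss", "evaluate", "run_protocol", "algorithm_summary"]


def auc(labels, scores, weights=None) -> float:
    """Rank-based (Mann–Whitney) ROC AUC; tied scores contribute 1/2.

    Raises on one-class input.
    """
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: labels contain a single class")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float),
                               sample_weight=weights))


@dataclass(frozen=True)
class EvalScores:
    auc: float
    tss: float
    tss_threshold: float


def tss(labels, scores) -> tuple[float, float]:
    """Maximum True Skill Statistic over a data-driven threshold sweep.

    Candidate thresholds are the midpoints of consecutive sorted unique scores
    plus 0 and 1; a point is predicted present iff its score exceeds the
    threshold.  Returns ``(max TSS, smallest argmax threshold)``.
    """
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("TSS undefined: labels contain a single class")
    uniq = np.unique(scores)
    cand = np.concatenate([[0.0], (uniq[:-1] + uniq[1:]) / 2.0, [1.0]])
    cand = np.unique(cand)
    n_pos = (labels == 1).sum()
    n_neg = (labels == 0).sum()
    pred = scores[None, :] > cand[:, None]          # (n_thresholds, n_points)
    tp = (pred & (labels == 1)).sum(axis=1)
    tn = (~pred & (labels == 0)).sum(axis=1)
    stat = tp / n_pos + tn / n_neg - 1.0
    best = int(np.argmax(stat))                     # argmax -> smallest threshold on ties
    return float(stat[best]), float(cand[best])


def evaluate(labels, scores) -> EvalScores:
    t, thr = tss(labels, scores)
    return EvalScores(auc=auc(labels, scores), tss=t, tss_threshold=thr)


def run_protocol(
    datasets: list[ModelingDataset],
    specs: list[LearnerSpec],
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Fit/score every (algorithm × pseudo-absence set × repetition).

    Each member is fitted on the repetition's 75 % train fold with the dataset
    weights (where supported) and scored unweighted on the 25 % test fold.
    Failures are recorded with status ``"failed"``, never raised.  Returns the
    member table and a dict of fitted models keyed ``(algorithm, pa_set, rep)``.
    """
    if not datasets or not specs:
        raise ValueError("run_protocol needs at least one dataset and one learner")
    rows = []
    models: dict[tuple[str, int, int], object] = {}
    for spec in specs:
        for ds in datasets:
            for rep in range(ds.n_reps):
                tr, te = ds.fold(rep)
                rec = {"algorithm": spec.name, "pa_set": ds.pa_set_id, "rep": rep,
                       "status": "ok", "auc": np.nan, "tss": np.nan,
                       "tss_threshold": np.nan}
                # distinct, reproducible stream per member
                rs = seed + 7919 * rep + 104729 * ds.pa_set_id
                try:
                    model = make_learner(spec, random_state=rs)
                    model.fit(ds.X[tr], ds.y[tr], sample_weight=ds.w[tr])
                    sc = evaluate(ds.y[te], model.predict(ds.X[te]))
                    rec.update(auc=sc.auc, tss=sc.tss, tss_threshold=sc.tss_threshold)
                    models[(spec.name, ds.pa_set_id, rep)] = model
                except Exception as exc:  # noqa: BLE001 — member failure is data, not a crash
                    rec["status"] = "failed"
                    rec["error"] = str(exc)
                rows.append(rec)
    return pd.DataFrame(rows), models


def algorithm_summary(member_table: pd.DataFrame) -> pd.DataFrame:
    """Per-algorithm mean AUC/TSS over ok runs, plus run/failure counts."""
    ok = member_table[member_table["status"] == "ok"]
    g = ok.groupby("algorithm").agg(mean_auc=("auc", "mean"), mean_tss=("tss", "mean"),
                                    n_ok=("auc", "size"))
    fails = member_table[member_table["status"] == "failed"].groupby("algorithm").size()
    g["n_failed"] = fails.reindex(g.index).fillna(0).astype(int)
    missing = set(member_table["algorithm"]) - set(g.index)
    for alg in sorted(missing):   # algorithms with zero ok runs
        g.loc[alg] = [np.nan, np.nan, 0, int((member_table["algorithm"] == alg).sum())]
    return g.reset_index()
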