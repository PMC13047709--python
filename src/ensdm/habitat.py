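"""Habitat products derived from suitability grids.

From a per-cell suitability P in [0, 1] this module derives:

* grade maps — 1 unsuitable (0 ≤ P ≤ 0.3), 2 low (0.3 < P ≤ 0.6),
  3 moderate (0.6 < P ≤ 0.85), 4 high (0.85 < P ≤ 1);
* binary presence/absence maps (presence iff P > 0.3; exactly 0.3 is absence,
  consistent with the grading rule);
* per-class area tables (reported in 10⁴ km², rounded to 2 decimals only at
  the reporting layer);
* gain/loss/retained/absent change maps between two periods, with expansion
  and contraction rates relative to the previous-period suitable baseline
  (= retained + loss);
* grade-transition maps coded X = A·10 + B with the 4×4 area cross-tabulation;
* latitude/longitude/elevation area profiles by grade.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import AreaModel, EnvStack, GridSpec, area_grid

__all__ = [
    "SuitabilityMap",
    "classify",
    "binarize",
    "areas",
    "change",
    "rates",
    "transition_code",
    "profiles",
    "suitable_mask",
    "REPORT_UNIT",
]

GRADE_NAMES = {1: "unsuitable", 2: "low", 3: "moderate", 4: "high"}
CHANGE_CODES = {"absent": 0, "gain": 1, "loss": 2, "retained": 3}
REPORT_UNIT = 1.0e4  # areas reported in 10^4 km^2


@dataclass
class SuitabilityMap:
    spec: GridSpec
    P: np.ndarray          # NaN on masked cells
    scenario_id: str = "current"

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        valid = np.isfinite(self.P)
        if valid.any() and ((self.P[valid] < 0) | (self.P[valid] > 1)).any():
            raise ValueError("suitability values must lie in [0, 1]")

    @property
    def mask(self) -> np.ndarray:
        return np.isfinite(self.P)


def classify(P: np.ndarray) -> np.ndarray:
    """Grade codes 1–4 from suitability; 0 on masked (NaN) cells.

    Interval edges are inclusive on the right: P = 0.3 → 1, P = 0.6 → 2,
    P = 0.85 → 3.
    """
    P = np.asarray(P, dtype=float)
    valid = np.isfinite(P)
    if valid.any() and ((P[valid] < 0) | (P[valid] > 1)).any():
        raise ValueError("suitability values must lie in [0, 1]")
    codes = np.zeros(P.shape, dtype=int)
    codes[valid & (P <= 0.3)] = 1
    codes[valid & (P > 0.3) & (P <= 0.6)] = 2
    codes[valid & (P > 0.6) & (P <= 0.85)] = 3
    codes[valid & (P > 0.85)] = 4
    return codes


def binarize(P: np.ndarray, cut: float = 0.3) -> np.ndarray:
    """0/1 presence map: presence iff P > cut (P = cut → absence); -1 on masked cells."""
    P = np.asarray(P, dtype=float)
    out = np.where(np.isfinite(P), (P > cut).astype(int), -1)
    return out


def suitable_mask(P: np.ndarray, class_mode: str = "binary") -> np.ndarray:
    """Binary suitable map under either class definition.

    ``"binary"``: suitable iff P > 0.3 (grades ≥ 2).  ``"moderate+high"``:
    suitable iff grade ≥ 3 (P > 0.6), the definition behind the
    moderate-and-high change accounting.
    """
    if class_mode == "binary":
        return binarize(P, 0.3)
    if class_mode == "moderate+high":
        g = classify(P)
        return np.where(g == 0, -1, (g >= 3).astype(int))
    raise ValueError(f"unknown class_mode {class_mode!r}")


def _area_of(mask: np.ndarray, A: np.ndarray) -> float:
    return float(A[mask].sum())


def areas(grade_map: np.ndarray, spec: GridSpec, model: AreaModel) -> pd.DataFrame:
    """Per-grade areas (km²) with shares of the suitable total and the valid domain."""
    A = area_grid(spec, model)
    valid = grade_map > 0
    total_valid = _area_of(valid, A)
    per = {g: _area_of(grade_map == g, A) for g in (1, 2, 3, 4)}
    suit_total = per[2] + per[3] + per[4]
    rows = []
    for g in (1, 2, 3, 4):
        rows.append({
            "grade": g,
            "name": GRADE_NAMES[g],
            "area_km2": per[g],
            "pct_of_suitable": 100.0 * per[g] / suit_total if g >= 2 and suit_total > 0 else np.nan,
            "pct_of_domain": 100.0 * per[g] / total_valid if total_valid > 0 else np.nan,
        })
    df = pd.DataFrame(rows)
    df.attrs["total_valid_km2"] = total_valid
    df.attrs["total_suitable_km2"] = suit_total
    return df


def change(
    bin_prev: np.ndarray,
    bin_next: np.ndarray,
    spec: GridSpec,
    model: AreaModel,
) -> tuple[np.ndarray, dict[str, float]]:
    """Per-cell change category and the four area sums (km²).

    Categories: gain 0→1, loss 1→0, retained 1→1, absent 0→0; masked cells
    (coded -1 in either input) carry code -1 and enter no sum.
    """
    bin_prev = np.asarray(bin_prev)
    bin_next = np.asarray(bin_next)
    if bin_prev.shape != bin_next.shape:
        raise ValueError("change: maps are not aligned")
    A = area_grid(spec, model)
    valid = (bin_prev >= 0) & (bin_next >= 0)
    cat = np.full(bin_prev.shape, -1, dtype=int)
    cat[valid & (bin_prev == 0) & (bin_next == 0)] = CHANGE_CODES["absent"]
    cat[valid & (bin_prev == 0) & (bin_next == 1)] = CHANGE_CODES["gain"]
    cat[valid & (bin_prev == 1) & (bin_next == 0)] = CHANGE_CODES["loss"]
    cat[valid & (bin_prev == 1) & (bin_next == 1)] = CHANGE_CODES["retained"]
    sums = {name: _area_of(cat == code, A) for name, code in CHANGE_CODES.items()}
    return cat, sums


def rates(gain_area: float, loss_area: float, retained_area: float) -> dict[str, float]:
    """Expansion and contraction rates (%) relative to the previous-period
    suitable baseline (retained + loss)."""
    baseline = retained_area + loss_area
    if not baseline > 0:
        raise ZeroDivisionError("rate undefined: previous-period suitable area is zero")
    return {
        "expansion_rate_pct": 100.0 * gain_area / baseline,
        "contraction_rate_pct": 100.0 * loss_area / baseline,
    }


def transition_code(
    grade_prev: np.ndarray,
    grade_next: np.ndarray,
    spec: GridSpec,
    model: AreaModel,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-cell transition code X = A·10 + B and the 4×4 area matrix (km²).

    Rows of the matrix are the previous-period grade A, columns the
    subsequent-period grade B.
    """
    grade_prev = np.asarray(grade_prev)
    grade_next = np.asarray(grade_next)
    if grade_prev.shape != grade_next.shape:
        raise ValueError("transition: maps are not aligned")
    valid = (grade_prev > 0) & (grade_next > 0)
    bad = valid & ((grade_prev > 4) | (grade_next > 4))
    if bad.any():
        raise ValueError("grade codes outside {1..4}")
    X = np.where(valid, grade_prev * 10 + grade_next, -1)
    A = area_grid(spec, model)
    mat = np.zeros((4, 4))
    for a in range(1, 5):
        for b in range(1, 5):
            mat[a - 1, b - 1] = _area_of(X == a * 10 + b, A)
    labels = [GRADE_NAMES[g] for g in (1, 2, 3, 4)]
    return X, pd.DataFrame(mat, index=labels, columns=labels)


def profiles(
    grade_map: np.ndarray,
    stack: EnvStack,
    model: AreaModel,
    axis: str = "latitude",
    n_bins: int = 20,
) -> pd.DataFrame:
    """Per-bin area (km²) by grade along latitude, longitude or elevation.

    Bins are equal-width over the observed axis range among valid cells; the
    elevation axis requires an ``elev`` layer.
    """
    spec = stack.spec
    A = area_grid(spec, model)
    valid = grade_map > 0
    if axis == "latitude":
        coord = np.repeat(spec.row_centre_latitudes()[:, None], spec.n_cols, axis=1)
    elif axis == "longitude":
        xs = spec.x_origin + (np.arange(spec.n_cols) + 0.5) * spec.cell_size
        coord = np.repeat(xs[None, :], spec.n_rows, axis=0)
    elif axis == "elevation":
        if "elev" not in stack:
            raise KeyError("elevation profile requires an 'elev' layer")
        coord = stack["elev"].values
    else:
        raise ValueError(f"unknown profile axis {axis!r}")
    vals = coord[valid]
    lo, hi = float(np.nanmin(vals)), float(np.nanmax(vals))
    if hi == lo:
        hi = lo + 1e-9
    edges = np.linspace(lo, hi, n_bins + 1)
    which = np.clip(np.digitize(coord, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        row = {"bin_left": edges[b], "bin_right": edges[b + 1]}
        sel = valid & (which == b)
        for g in (1, 2, 3, 4):
            row[GRADE_NAMES[g]] = _area_of(sel & (grade_map == g), A)
        rows.append(row)
    return pd.DataFrame(rows)


def report_round(area_km2: float) -> float:
    """Area in the reporting unit (10⁴ km²), rounded to 2 decimals."""
    return round(area_km2 / REPORT_UNIT, 2)
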