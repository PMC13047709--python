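"""Occurrence ingestion, spatial thinning, pseudo-absences and modelling datasets.

Presence-only occurrence records are thinned to a minimum inter-point distance
(1 km by default) to curb spatial sampling autocorrelation, paired with
randomly placed pseudo-absence points, weighted so that a prevalence of 0.5
equalises the total class weights, and split into stratified 75/25
train/test repetitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .grid import EnvStack, extract

__all__ = [
    "OccurrenceSet",
    "ThinningSpec",
    "PseudoAbsenceSpec",
    "ModelingDataset",
    "read_occurrences",
    "write_occurrences",
    "thin",
    "sample_pseudo_absences",
    "assemble",
    "haversine_km",
]

EARTH_RADIUS_KM = 6371.0


@dataclass
class OccurrenceSet:
    """Georeferenced presence records for one species."""

    lon: np.ndarray
    lat: np.ndarray
    species: str = "species"
    source: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        if self.lon.shape != self.lat.shape:
            raise ValueError("lon and lat must have equal length")
        if not (np.isfinite(self.lon).all() and np.isfinite(self.lat).all()):
            raise ValueError("occurrence coordinates must be finite")
        if self.source is None:
            self.source = np.full(len(self.lon), "", dtype=object)

    def __len__(self) -> int:
        return len(self.lon)

    def take(self, idx) -> "OccurrenceSet":
        return OccurrenceSet(self.lon[idx], self.lat[idx], self.species, self.source[idx])


def read_occurrences(path: str | Path) -> OccurrenceSet:
    """Read a "species,longitude,latitude[,source]" CSV; drops non-finite rows."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    lon = pd.to_numeric(df[cols["longitude"]], errors="coerce")
    lat = pd.to_numeric(df[cols["latitude"]], errors="coerce")
    keep = lon.notna() & lat.notna()
    species = str(df[cols["species"]].iloc[0]) if len(df) else "species"
    src = df[cols["source"]].astype(str).to_numpy() if "source" in cols else None
    src = src[keep.to_numpy()] if src is not None else None
    return OccurrenceSet(lon[keep].to_numpy(), lat[keep].to_numpy(), species, src)


def write_occurrences(occ: OccurrenceSet, path: str | Path) -> None:
    pd.DataFrame(
        {
            "species": occ.species,
            "longitude": occ.lon,
            "latitude": occ.lat,
            "source": occ.source,
        }
    ).to_csv(path, index=False)


@dataclass(frozen=True)
class ThinningSpec:
    """Minimum-distance thinning parameters."""

    radius_km: float = 1.0
    seed: int = 0
    distance_mode: str = "great-circle"  # or "euclidean" (coords in km)

    def __post_init__(self) -> None:
        if not self.radius_km > 0:
            raise ValueError("radius_km must be positive")
        if self.distance_mode not in ("great-circle", "euclidean"):
            raise ValueError(f"unknown distance_mode {self.distance_mode!r}")


def haversine_km(lon1, lat1, lon2, lat2, radius_km: float = EARTH_RADIUS_KM) -> np.ndarray:
    """Great-circle distance in km between (lon1,lat1) and (lon2,lat2) in degrees."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * radius_km * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def _distances(spec: ThinningSpec, lon, lat, lon2, lat2) -> np.ndarray:
    if spec.distance_mode == "great-circle":
        return haversine_km(lon, lat, lon2, lat2)
    return np.hypot(np.asarray(lon) - lon2, np.asarray(lat) - lat2)


def thin(occ: OccurrenceSet, spec: ThinningSpec = ThinningSpec()) -> OccurrenceSet:
    """Greedy minimum-distance thinning.

    Records are visited in a seeded random order; a record is kept iff its
    distance to every already-kept record exceeds ``radius_km``.  The result
    therefore satisfies the pairwise-separation property exactly, while the
    particular maximal set kept depends (deterministically) on the seed.
    """
    n = len(occ)
    if n == 0:
        raise ValueError("cannot thin an empty occurrence set")
    order = np.random.default_rng(spec.seed).permutation(n)
    kept: list[int] = []
    for i in order:
        if not kept:
            kept.append(i)
            continue
        d = _distances(spec, occ.lon[kept], occ.lat[kept], occ.lon[i], occ.lat[i])
        if np.all(d > spec.radius_km):
            kept.append(i)
    kept_arr = np.sort(np.asarray(kept))
    return occ.take(kept_arr)


@dataclass(frozen=True)
class PseudoAbsenceSpec:
    """Pseudo-absence sampling parameters (paper protocol: 1000 points × 2 sets)."""

    n_points: int = 1000
    n_sets: int = 2
    seed: int = 0
    exclude_presence_cells: bool = True

    def __post_init__(self) -> None:
        if self.n_points < 1 or self.n_sets < 1:
            raise ValueError("n_points and n_sets must be positive")


def sample_pseudo_absences(
    stack: EnvStack,
    presences: OccurrenceSet,
    spec: PseudoAbsenceSpec = PseudoAbsenceSpec(),
) -> list[OccurrenceSet]:
    """Uniform without-replacement sampling of valid, non-presence cells.

    Each of the ``n_sets`` sets is drawn with its own derived seed
    (``seed + set_index``); points are placed at cell centres.
    """
    gs = stack.spec
    eligible = stack.mask.copy()
    if spec.exclude_presence_cells:
        for x, y in zip(presences.lon, presences.lat):
            cell = gs.cell_of(x, y)
            if cell is not None:
                eligible[cell] = False
    rows, cols = np.nonzero(eligible)
    n_elig = len(rows)
    if spec.n_points > n_elig:
        raise ValueError(
            f"requested {spec.n_points} pseudo-absences but only {n_elig} eligible cells"
        )
    out = []
    for s in range(spec.n_sets):
        rng = np.random.default_rng(spec.seed + s)
        idx = rng.choice(n_elig, size=spec.n_points, replace=False)
        xs, ys = zip(*(gs.cell_centre(r, c) for r, c in zip(rows[idx], cols[idx])))
        out.append(
            OccurrenceSet(np.asarray(xs), np.asarray(ys), presences.species,
                          np.full(spec.n_points, "pseudo-absence", dtype=object))
        )
    return out


@dataclass
class ModelingDataset:
    """Presences + one pseudo-absence set with predictors, weights and splits."""

    X: np.ndarray
    y: np.ndarray
    w: np.ndarray
    var_names: list[str]
    pa_set_id: int = 0
    prevalence: float = 0.5
    rep_assignments: list[np.ndarray] = field(default_factory=list)  # boolean train masks

    @property
    def n_reps(self) -> int:
        return len(self.rep_assignments)

    def fold(self, rep: int) -> tuple[np.ndarray, np.ndarray]:
        """(train_mask, test_mask) for one repetition."""
        tr = self.rep_assignments[rep]
        return tr, ~tr


def _train_size(n: int, train_frac: float) -> int:
    """round(train_frac·n) with half-up rounding; at least 1 test and 1 train point."""
    k = int(math.floor(train_frac * n + 0.5))
    k = min(k, n - 1)  # keep >= 1 test point
    return max(k, 1)


def _stratified_splits(y: np.ndarray, n_reps: int, train_frac: float, seed: int) -> list[np.ndarray]:
    masks = []
    pres = np.nonzero(y == 1)[0]
    absn = np.nonzero(y == 0)[0]
    if len(pres) < 4:
        raise ValueError(f"need at least 4 presences to form 75/25 splits, got {len(pres)}")
    k_p = _train_size(len(pres), train_frac)
    k_a = _train_size(len(absn), train_frac)
    for rep in range(n_reps):
        rng = np.random.default_rng(seed + rep)
        tr = np.zeros(len(y), dtype=bool)
        tr[rng.permutation(pres)[:k_p]] = True
        tr[rng.permutation(absn)[:k_a]] = True
        masks.append(tr)
    return masks


def assemble(
    stack: EnvStack,
    presences: OccurrenceSet,
    pa_sets: Sequence[OccurrenceSet],
    var_names: Sequence[str] | None = None,
    prevalence: float = 0.5,
    n_reps: int = 10,
    train_frac: float = 0.75,
    seed: int = 0,
) -> list[ModelingDataset]:
    """Build one :class:`ModelingDataset` per pseudo-absence set.

    Presences carry weight 1; each pseudo-absence carries
    ``(n_presence/n_pa)·(prevalence/(1−prevalence))`` so that at prevalence 0.5
    the two classes have equal total weight.  Points falling in masked cells or
    outside the grid are dropped (their count is available from the returned
    dataset sizes).
    """
    var_names = list(var_names) if var_names is not None else stack.layer_names
    Xp, stat_p = extract(stack, presences.lon, presences.lat, var_names)
    ok_p = stat_p == "ok"
    Xp = Xp[ok_p]
    datasets = []
    for k, pa in enumerate(pa_sets):
        Xa, stat_a = extract(stack, pa.lon, pa.lat, var_names)
        ok_a = stat_a == "ok"
        Xa = Xa[ok_a]
        n_p, n_a = len(Xp), len(Xa)
        if n_a == 0:
            raise ValueError("pseudo-absence set has no usable points")
        w_pa = (n_p / n_a) * (prevalence / (1.0 - prevalence))
        X = np.vstack([Xp, Xa])
        y = np.concatenate([np.ones(n_p, dtype=int), np.zeros(n_a, dtype=int)])
        w = np.concatenate([np.ones(n_p), np.full(n_a, w_pa)])
        reps = _stratified_splits(y, n_reps, train_frac, seed + 1000 * k)
        datasets.append(
            ModelingDataset(X, y, w, var_names, pa_set_id=k, prevalence=prevalence,
                            rep_assignments=reps)
        )
    return datasets
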