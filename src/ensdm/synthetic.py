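"""Synthetic landscapes with a known truth surface.

The generator emulates the structure of a bioclimatic modelling exercise
without any external data: spatially smooth, partially inter-correlated
environmental layers; a logistic truth suitability surface on a small active
subset of those layers; presences sampled proportionally to truth; and
deterministic per-layer "scenario shifts" that stand in for future climate
stacks, including shifts that push cells beyond the reference range to
exercise MESS extrapolation.

All randomness flows from a single master seed; stage seeds are derived by
fixed offsets (stack = seed, presence sampling = seed + 1, jitter = seed + 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq

from .grid import EnvStack, GridSpec, Layer
from .occurrences import OccurrenceSet

__all__ = [
    "TruthSpec",
    "ScenarioShift",
    "gen_stack",
    "true_suitability",
    "sample_presences",
    "future_stack",
    "default_fixture",
    "DEFAULT_LAYER_NAMES",
    "DEFAULT_TRUTH",
    "DEFAULT_CORRELATION_PAIRS",
]

# 12 layers: ten climate-style variables plus terrain, matching the kind of
# stack the pipeline ingests (an "elev" layer is required by elevation profiles)
DEFAULT_LAYER_NAMES = [
    "bio1", "bio2", "bio3", "bio4", "bio5", "bio6", "bio7", "bio8",
    "bio9", "bio10", "elev", "slope",
]

# near-duplicate pairs (source, copy, target |r|) to exercise screening;
# each copy shadows an active truth variable
DEFAULT_CORRELATION_PAIRS = [("bio1", "bio9", 0.97), ("bio2", "bio10", 0.95)]


@dataclass(frozen=True)
class TruthSpec:
    """Logistic truth surface on standardized layers.

    P = logistic(β0 + Σ β_j z_j + Σ γ_j z_j²) with z the per-layer z-score
    over valid cells.  When ``target_prevalence`` is set, β0 is calibrated per
    realization (by root finding) so that the landscape-mean suitability
    equals the target — the standard virtual-species device that keeps the
    niche size comparable across random landscapes; ``intercept`` is then
    ignored.
    """

    intercept: float = 0.0
    betas: tuple = ()
    gammas: tuple = ()
    target_prevalence: float | None = None

    def __post_init__(self) -> None:
        if not (dict(self.betas) or dict(self.gammas)):
            raise ValueError("truth needs at least one nonzero coefficient")
        if self.target_prevalence is not None and not 0 < self.target_prevalence < 1:
            raise ValueError("target_prevalence must lie in (0, 1)")

    @classmethod
    def of(cls, intercept: float = 0.0, betas: dict | None = None,
           gammas: dict | None = None, target_prevalence: float | None = None) -> "TruthSpec":
        return cls(intercept,
                   tuple(sorted((betas or {}).items())),
                   tuple(sorted((gammas or {}).items())),
                   target_prevalence)

    @property
    def active_variables(self) -> list[str]:
        return sorted(set(dict(self.betas)) | set(dict(self.gammas)))


# truth uses 3 of the 12 layers; bio1 is unimodal (negative quadratic, a
# temperature-optimum response), bio2 and elev act linearly.  Steep
# coefficients give a sharply bounded niche, and the landscape-mean
# suitability is pinned at 6.5 % — the suitable share of a strongly
# climate-limited species occupying a small fraction of a large domain.
DEFAULT_TRUTH = TruthSpec.of(
    betas={"bio1": 12.0, "bio2": -7.0, "elev": -5.0},
    gammas={"bio1": -6.0},
    target_prevalence=0.065,
)


@dataclass(frozen=True)
class ScenarioShift:
    """Deterministic per-layer affine change x → scale·x + offset."""

    label: str
    offsets: tuple = ()
    scales: tuple = ()

    @classmethod
    def of(cls, label: str, offsets: dict | None = None,
           scales: dict | None = None) -> "ScenarioShift":
        return cls(label,
                   tuple(sorted((offsets or {}).items())),
                   tuple(sorted((scales or {}).items())))


def _smooth_field(shape: tuple[int, int], smoothness: float, rng: np.random.Generator) -> np.ndarray:
    z = gaussian_filter(rng.standard_normal(shape), sigma=smoothness, mode="reflect")
    sd = z.std()
    return (z - z.mean()) / (sd if sd > 0 else 1.0)


def gen_stack(
    spec: GridSpec | None = None,
    layer_names: list[str] | None = None,
    smoothness: float = 6.0,
    correlation_pairs=DEFAULT_CORRELATION_PAIRS,
    seed: int = 0,
    scenario_id: str = "current",
) -> EnvStack:
    """Generate a stack of smooth random fields with engineered correlations.

    Each layer is Gaussian-filtered white noise (kernel width ``smoothness``
    in cells), standardized to mean 0 / sd 1.  For each
    ``(source, copy, r)`` correlation pair, the copy layer is rebuilt as
    ``r·source + sqrt(1−r²)·independent`` so the realized correlation is close
    to the target.
    """
    spec = spec or GridSpec(120, 120)
    names = list(layer_names) if layer_names is not None else list(DEFAULT_LAYER_NAMES)
    rng = np.random.default_rng(seed)
    shape = (spec.n_rows, spec.n_cols)
    fields = {nm: _smooth_field(shape, smoothness, rng) for nm in names}
    for src, dup, r in correlation_pairs:
        if src not in fields or dup not in fields:
            raise KeyError(f"correlation pair ({src}, {dup}) not among layers")
        indep = _smooth_field(shape, smoothness, rng)
        fields[dup] = r * fields[src] + np.sqrt(1.0 - r * r) * indep
    layers = [Layer(nm, fields[nm]) for nm in names]
    return EnvStack(spec, layers, scenario_id)


def _score(stack: EnvStack, truth: TruthSpec, reference: EnvStack) -> np.ndarray:
    """Linear+quadratic truth score on layers z-scored by *reference* statistics."""
    betas, gammas = dict(truth.betas), dict(truth.gammas)
    score = np.zeros((stack.spec.n_rows, stack.spec.n_cols))
    for nm in truth.active_variables:
        ref = reference[nm].values
        mu, sd = np.nanmean(ref), np.nanstd(ref)
        Z = (stack[nm].values - mu) / (sd if sd > 0 else 1.0)
        score = score + betas.get(nm, 0.0) * Z + gammas.get(nm, 0.0) * Z ** 2
    return score


def true_suitability(
    stack: EnvStack,
    truth: TruthSpec = DEFAULT_TRUTH,
    reference: EnvStack | None = None,
) -> np.ndarray:
    """Truth suitability grid P in (0, 1); NaN on masked cells.

    When rescoring a shifted scenario stack, pass the unshifted stack as
    ``reference`` so that the standardization and the prevalence-calibrated
    intercept stay those of the reference period (otherwise the calibration
    would re-pin the prevalence and hide the shift).
    """
    names = truth.active_variables
    missing = [nm for nm in names if nm not in stack]
    if missing:
        raise KeyError(f"truth variables missing from stack: {missing}")
    ref = reference if reference is not None else stack
    score = _score(stack, truth, ref)
    if truth.target_prevalence is not None:
        s_ref = _score(ref, truth, ref)[ref.mask]

        def mean_p(ic: float) -> float:
            return float(np.mean(1.0 / (1.0 + np.exp(-(ic + s_ref))))) - truth.target_prevalence

        intercept = brentq(mean_p, -80.0, 80.0)
    else:
        intercept = truth.intercept
    P = 1.0 / (1.0 + np.exp(-(intercept + score)))
    return np.where(stack.mask, P, np.nan)


def sample_presences(
    truth_map: np.ndarray,
    spec: GridSpec,
    n: int,
    seed: int = 0,
    jitter: float = 0.3,
    species: str = "synthetic-species",
) -> OccurrenceSet:
    """Draw presence cells without replacement with probability ∝ truth P.

    Points sit at cell centres plus uniform sub-cell jitter (±``jitter``·cell)
    so that spatial thinning has something to do.
    """
    valid = np.isfinite(truth_map)
    rows, cols = np.nonzero(valid)
    p = truth_map[valid].astype(float)
    if n > len(rows):
        raise ValueError(f"requested {n} presences from {len(rows)} valid cells")
    p = p / p.sum()
    rng = np.random.default_rng(seed + 1)
    idx = rng.choice(len(rows), size=n, replace=False, p=p)
    jit = np.random.default_rng(seed + 2)
    xs, ys = [], []
    for r, c in zip(rows[idx], cols[idx]):
        x, y = spec.cell_centre(r, c)
        xs.append(x + jit.uniform(-jitter, jitter) * spec.cell_size)
        ys.append(y + jit.uniform(-jitter, jitter) * spec.cell_size)
    return OccurrenceSet(np.asarray(xs), np.asarray(ys), species)


def future_stack(stack: EnvStack, shift: ScenarioShift) -> EnvStack:
    """Apply a deterministic affine shift per named layer; identity elsewhere."""
    offsets, scales = dict(shift.offsets), dict(shift.scales)
    unknown = (set(offsets) | set(scales)) - set(stack.layer_names)
    if unknown:
        raise KeyError(f"shift names layers not in stack: {sorted(unknown)}")
    layers = []
    for lay in stack.layers:
        v = lay.values * scales.get(lay.name, 1.0) + offsets.get(lay.name, 0.0)
        layers.append(Layer(lay.name, v, lay.units))
    return EnvStack(stack.spec, layers, shift.label)


def default_fixture(
    seed: int = 0,
    n_rows: int = 120,
    n_cols: int = 120,
    n_presences: int = 300,
    truth: TruthSpec = DEFAULT_TRUTH,
) -> dict:
    """The standard synthetic study: current stack, truth, presences and two
    future scenarios (a mild warming shift and a beyond-range shift).

    Returns a dict with keys ``stack``, ``truth_map``, ``presences``,
    ``futures`` (list of EnvStack) and ``truth``.
    """
    spec = GridSpec(n_rows, n_cols)
    stack = gen_stack(spec, seed=seed)
    truth_map = true_suitability(stack, truth)
    occ = sample_presences(truth_map, spec, n_presences, seed=seed)
    futures = [
        future_stack(stack, ScenarioShift.of("warm+0.5", offsets={"bio1": 0.5})),
        # bio2 offset far beyond its standardized range: forces MESS S <= 0
        future_stack(stack, ScenarioShift.of("extreme", offsets={"bio2": 10.0})),
    ]
    return {"stack": stack, "truth_map": truth_map, "presences": occ,
            "futures": futures, "truth": truth}
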