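import numpy as np
import pytest

from ensdm.grid import GridSpec
from ensdm.occurrences import (OccurrenceSet, PseudoAbsenceSpec, ThinningSpec,
                               assemble, sample_pseudo_absences, thin)
from ensdm.synthetic import gen_stack


@pytest.fixture(scope="session")
def small_stack():
    """40x40 abstract stack with the default 12 layers and duplicate pairs."""
    return gen_stack(GridSpec(40, 40), seed=7)


@pytest.fixture(scope="session")
def toy_dataset(small_stack):
    """One modelling dataset on the small stack: ~80 presences, 150 PAs, 3 reps."""
    rng = np.random.default_rng(3)
    # presences biased toward high bio1 cells so learners have signal
    v = small_stack["bio1"].values
    rows, cols = np.nonzero(small_stack.mask)
    p = np.exp(2.0 * (v[rows, cols] - v[rows, cols].mean()) / v[rows, cols].std())
    p /= p.sum()
    idx = rng.choice(len(rows), 80, replace=False, p=p)
    xs, ys = zip(*(small_stack.spec.cell_centre(r, c) for r, c in zip(rows[idx], cols[idx])))
    occ = OccurrenceSet(np.asarray(xs), np.asarray(ys))
    pas = sample_pseudo_absences(small_stack, occ, PseudoAbsenceSpec(150, 1, seed=5))
    return assemble(small_stack, occ, pas, n_reps=3, seed=11)[0]


class LinearScorer:
    """Deterministic stand-in model: predict = sigmoid(X @ coef)."""

    def __init__(self, coef):
        self.coef = np.asarray(coef, dtype=float)

    def predict(self, X):
        return 1.0 / (1.0 + np.exp(-(np.asarray(X, dtype=float) @ self.coef)))


class ConstantScorer:
    def __init__(self, value=0.5):
        self.value = value

    def predict(self, X):
        return np.full(len(X), self.value)


@pytest.fixture
def linear_scorer():
    return LinearScorer
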