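import numpy as np
import pytest

from ensdm.learners import (DEFAULT_FC_GRID, DEFAULT_RM_GRID, FeatureExpander,
                            LearnerSpec, MaxentModel, SurfaceRangeEnvelope,
                            aicc, make_learner, tune_maxnet)
from ensdm.metrics import auc


def _presence_background(n_pres=200, n_bg=400, seed=0, coef=(4.0, -2.0)):
    """Logistic truth on 2 standard-normal variables."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n_pres + n_bg, len(coef)))
    p = 1 / (1 + np.exp(-(X @ np.asarray(coef))))
    y = (rng.uniform(size=len(p)) < p).astype(int)
    # ensure both classes well represented
    return X, y


class TestSRE:
    def test_q0_min_max_box(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [0.5, 0.2]])
        y = np.ones(3)
        sre = SurfaceRangeEnvelope(q=0.0).fit(X, y)
        assert sre.predict([[0.5, 0.5]])[0] == 1.0
        assert sre.predict([[1.5, 0.5]])[0] == 0.0

    def test_predictions_binary(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 3))
        sre = SurfaceRangeEnvelope().fit(X, np.ones(50))
        assert set(np.unique(sre.predict(rng.normal(size=(200, 3))))) <= {0.0, 1.0}

    def test_envelope_matches_sorting_oracle(self):
        """41 points per axis and q=0.025: (n-1)q = 1 exactly, so the bounds
        equal the 2nd smallest / 2nd largest order statistics."""
        rng = np.random.default_rng(2)
        X = rng.uniform(size=(41, 2))
        sre = SurfaceRangeEnvelope(q=0.025).fit(X, np.ones(41))
        srt = np.sort(X, axis=0)
        assert np.allclose(sre.lower_, srt[1])
        assert np.allclose(sre.upper_, srt[-2])

    def test_invalid_quantile_rejected(self):
        with pytest.raises(ValueError):
            SurfaceRangeEnvelope(q=0.5).fit(np.zeros((3, 1)), np.ones(3))


def _expected_n_features(fc, p, h, t):
    n = 0
    n += p if "L" in fc else 0
    n += p if "Q" in fc else 0
    n += 2 * h * p if "H" in fc else 0
    n += p * (p - 1) // 2 if "P" in fc else 0
    n += t * p if "T" in fc else 0
    return n


class TestFeatureExpansion:
    @pytest.mark.parametrize("fc,expected", [("L", 3), ("LQ", 6), ("LQHP", 309)])
    def test_counting_examples(self, fc, expected):
        X = np.random.default_rng(0).uniform(size=(30, 3))
        ex = FeatureExpander(fc, n_hinge_knots=50).fit(X)
        F, classes = ex.transform(X)
        assert F.shape[1] == expected == ex.n_features() == len(classes)

    @pytest.mark.parametrize("fc", list(DEFAULT_FC_GRID) + ["T", "PT", "QHT"])
    @pytest.mark.parametrize("p", [2, 5])
    def test_count_matches_closed_form(self, fc, p):
        X = np.random.default_rng(1).uniform(size=(25, p))
        ex = FeatureExpander(fc, n_hinge_knots=7, n_threshold_knots=4).fit(X)
        F, _ = ex.transform(X)
        assert F.shape[1] == _expected_n_features(fc, p, 7, 4)

    def test_degenerate_variable_skipped_with_warning(self):
        X = np.column_stack([np.ones(20), np.linspace(0, 1, 20)])
        with pytest.warns(UserWarning, match="degenerate"):
            ex = FeatureExpander("L").fit(X)
        F, _ = ex.transform(X)
        assert F.shape[1] == 1

    def test_empty_or_unknown_fc_rejected(self):
        with pytest.raises(ValueError):
            FeatureExpander("")
        with pytest.raises(ValueError):
            FeatureExpander("LX")


class TestMaxent:
    def test_separable_data_tiny_rm_training_auc_one(self):
        rng = np.random.default_rng(0)
        X = np.concatenate([rng.uniform(0.6, 1.0, 60), rng.uniform(0.0, 0.4, 120)])[:, None]
        y = np.concatenate([np.ones(60, int), np.zeros(120, int)])
        m = MaxentModel(fc="L", rm=1e-4).fit(X, y)
        assert auc(y, m.predict(X)) == 1.0

    def test_huge_rm_collapses_to_constant(self):
        X, y = _presence_background(seed=1)
        m = MaxentModel(fc="LQ", rm=1e6).fit(X, y)
        assert m.n_nonzero_coefs_ == 0
        assert np.ptp(m.predict(X)) == pytest.approx(0.0)

    def test_linear_coefficient_recovery(self):
        """Truth logistic(4x1 - 2x2): signs recovered and ratio ~2 (±30 %)."""
        X, y = _presence_background(n_pres=0, n_bg=500, seed=3)
        m = MaxentModel(fc="L", rm=0.1).fit(X, y)
        # with FC=L the two coefficients act on min-max scaled x1, x2
        c = m.coef_
        assert c[0] > 0 > c[1]
        assert abs(c[0] / c[1]) == pytest.approx(2.0, rel=0.3)

    def test_predictions_bounded_finite(self):
        X, y = _presence_background(seed=4)
        m = MaxentModel(fc="LQH", rm=1.0, n_hinge_knots=10).fit(X, y)
        p = m.predict(np.random.default_rng(0).normal(size=(100, 2)) * 5)
        assert np.isfinite(p).all() and (p >= 0).all() and (p <= 1).all()

    def test_too_few_presences_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 2))
        y = np.r_[np.ones(5, int), np.zeros(15, int)]
        with pytest.raises(ValueError, match="presences"):
            MaxentModel().fit(X, y)


class _StubModel:
    """Fixed suitability scores and coefficient count, for AICc arithmetic."""

    def __init__(self, scores, k):
        self._scores = np.asarray(scores, float)
        self._k = k

    @property
    def n_nonzero_coefs_(self):
        return self._k

    def predict(self, X):
        return self._scores


class TestAicc:
    def test_matches_direct_normalisation_oracle(self):
        rng = np.random.default_rng(5)
        scores = rng.uniform(0.01, 1.0, size=50)
        y = np.r_[np.ones(10, int), np.zeros(40, int)]
        k = 3
        got = aicc(_StubModel(scores, k), np.zeros((50, 1)), y)
        p = scores / scores.sum()
        lnL = np.log(p[:10]).sum()
        n = 10
        expected = 2 * k - 2 * lnL + 2 * k * (k + 1) / (n - k - 1)
        assert got == pytest.approx(expected, rel=1e-12)
        # spot-check the arithmetic shape: k=3, n=10, lnL=-25 -> 6 + 50 + 4 = 60
        assert 2 * 3 - 2 * (-25) + 2 * 3 * 4 / (10 - 3 - 1) == 60.0

    def test_k_equals_n_minus_one_invalid(self):
        y = np.r_[np.ones(5, int), np.zeros(10, int)]
        assert np.isnan(aicc(_StubModel(np.full(15, 0.5), 4), np.zeros((15, 1)), y))

    def test_monotone_penalty_at_equal_likelihood(self):
        scores = np.random.default_rng(6).uniform(0.1, 1.0, size=40)
        y = np.r_[np.ones(12, int), np.zeros(28, int)]
        a2 = aicc(_StubModel(scores, 2), None, y)
        a4 = aicc(_StubModel(scores, 4), None, y)
        assert a2 < a4


class TestTuning:
    def test_default_grids_enumerate_48_combinations(self):
        X, y = _presence_background(n_pres=0, n_bg=150, seed=7)
        res = tune_maxnet(X, y, rm_grid=DEFAULT_RM_GRID, fc_grid=DEFAULT_FC_GRID,
                          n_hinge_knots=4, n_threshold_knots=4, seed=0)
        assert len(res.table) == 48
        assert res.table["rm"].nunique() == 8
        assert res.table["fc"].nunique() == 6
        valid = res.table[res.table["valid"]]
        assert (valid["delta_aicc"] >= 0).all()
        chosen = res.table[(res.table.rm == res.chosen_rm) & (res.table.fc == res.chosen_fc)]
        assert chosen["delta_aicc"].iloc[0] == 0.0

    def test_single_combination_chosen(self):
        X, y = _presence_background(n_pres=0, n_bg=120, seed=8)
        res = tune_maxnet(X, y, rm_grid=[1.0], fc_grid=["LQ"], seed=0)
        assert (res.chosen_rm, res.chosen_fc) == (1.0, "LQ")

    def test_l_only_truth_prefers_simple_features(self):
        """On data generated by a purely linear logistic truth, AICc selection
        picks FC = L or LQ in at least 8 of 10 seeded replicates."""
        hits = 0
        for seed in range(10):
            X, y = _presence_background(n_pres=0, n_bg=220, seed=100 + seed,
                                        coef=(3.0, -1.5))
            res = tune_maxnet(X, y, rm_grid=[1.0], fc_grid=DEFAULT_FC_GRID,
                              n_hinge_knots=8, n_threshold_knots=8, seed=seed)
            hits += res.chosen_fc in ("L", "LQ")
        assert hits >= 8

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            tune_maxnet(np.zeros((10, 1)), np.zeros(10), rm_grid=[], fc_grid=["L"])


class TestRegistry:
    @pytest.mark.parametrize("name", ["ANN", "CTA", "FDA", "GAM", "GBM", "GLM",
                                      "MARS", "RF", "XGBOOST", "SRE"])
    def test_uniform_contract_bounds(self, name, toy_dataset):
        ds = toy_dataset
        tr, te = ds.fold(0)
        model = make_learner(LearnerSpec.of(name), random_state=0)
        model.fit(ds.X[tr], ds.y[tr], sample_weight=ds.w[tr])
        p = model.predict(ds.X[te])
        assert np.isfinite(p).all() and (p >= 0).all() and (p <= 1).all()

    def test_rf_separable_training_auc_one(self):
        X = np.r_[np.full((30, 1), 2.0), np.full((30, 1), -2.0)]
        y = np.r_[np.ones(30, int), np.zeros(30, int)]
        rf = make_learner(LearnerSpec.of("RF"), random_state=0).fit(X, y)
        assert auc(y, rf.predict(X)) == 1.0

    def test_glm_sign_recovery(self):
        X, y = _presence_background(n_pres=0, n_bg=500, seed=9)
        glm = make_learner(LearnerSpec.of("GLM")).fit(X, y)
        assert glm.coef_[0] > 0 > glm.coef_[1]

    def test_unknown_learner_rejected(self):
        with pytest.raises(ValueError, match="unknown learner"):
            LearnerSpec.of("KRIGING")

    def test_unknown_hyperparameter_rejected(self):
        with pytest.raises(TypeError):
            make_learner(LearnerSpec.of("RF", bogus=3))
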