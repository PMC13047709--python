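import numpy as np
import pandas as pd
import pytest

from ensdm.grid import AreaModel, EnvStack, GridSpec, Layer
from ensdm.habitat import (areas, binarize, change, classify, profiles, rates,
                           suitable_mask, transition_code)

CONST = AreaModel("constant", 1.0)


class TestClassify:
    @pytest.mark.parametrize("p,code", [(0.0, 1), (0.30, 1), (0.31, 2), (0.60, 2),
                                        (0.61, 3), (0.85, 3), (0.86, 4), (1.0, 4)])
    def test_breakpoints(self, p, code):
        assert classify(np.array([[p]]))[0, 0] == code

    def test_masked_cells_zero(self):
        g = classify(np.array([[np.nan, 0.5]]))
        assert g[0, 0] == 0 and g[0, 1] == 2

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            classify(np.array([[1.2]]))


class TestBinarize:
    def test_boundary_is_absence(self):
        out = binarize(np.array([[0.30, 0.31, 0.0, np.nan]]))
        assert list(out[0]) == [0, 1, 0, -1]

    def test_all_zero_map(self):
        assert (binarize(np.zeros((3, 3))) == 0).all()


class TestAreas:
    def test_counts_as_areas_on_unit_grid(self):
        g = np.ones((10, 10), dtype=int)
        g.flat[:40] = 2
        g.flat[40:50] = 3
        df = areas(g, GridSpec(10, 10), CONST).set_index("grade")
        assert df.loc[2, "area_km2"] == 40.0
        assert df.loc[3, "area_km2"] == 10.0
        assert df.loc[4, "area_km2"] == 0.0
        assert np.isnan(df.loc[1, "pct_of_suitable"])
        assert df.loc[2, "pct_of_suitable"] == pytest.approx(80.0)

    def test_shares_sum_to_hundred(self):
        rng = np.random.default_rng(0)
        g = rng.integers(1, 5, size=(20, 20))
        df = areas(g, GridSpec(20, 20), CONST)
        assert df["pct_of_suitable"].dropna().sum() == pytest.approx(100.0)
        assert df["pct_of_domain"].sum() == pytest.approx(100.0)


class TestChange:
    def test_identical_maps_no_gain_loss(self):
        b = np.random.default_rng(1).integers(0, 2, (8, 8))
        _, sums = change(b, b, GridSpec(8, 8), CONST)
        assert sums["gain"] == sums["loss"] == 0.0

    def test_all_gain(self):
        z, o = np.zeros((5, 5), int), np.ones((5, 5), int)
        _, sums = change(z, o, GridSpec(5, 5), CONST)
        assert sums["gain"] == 25.0

    def test_checkerboard_inversion_half_half(self):
        idx = np.indices((6, 6)).sum(axis=0) % 2
        _, sums = change(idx, 1 - idx, GridSpec(6, 6), CONST)
        assert sums["gain"] == sums["loss"] == 18.0

    @pytest.mark.parametrize("seed", range(3))
    def test_conservation_exact(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 2, (15, 15))
        b = rng.integers(0, 2, (15, 15))
        a[rng.uniform(size=a.shape) < 0.1] = -1  # masked
        cat, sums = change(a, b, GridSpec(15, 15), CONST)
        valid = (a >= 0) & (b >= 0)
        assert sum(sums.values()) == float(valid.sum())

    def test_misaligned_raises(self):
        with pytest.raises(ValueError):
            change(np.zeros((2, 2), int), np.zeros((3, 3), int), GridSpec(2, 2), CONST)


class TestRates:
    def test_printed_rate_identities(self):
        """Gain 10.75 / retained 22.37 / loss 2.08 reproduce the 43.97 %
        expansion over the 24.45 baseline; loss 7.31 on the same baseline
        gives 29.90 % contraction."""
        r = rates(10.75, 2.08, 22.37)
        assert round(r["expansion_rate_pct"], 2) == 43.97
        assert round(r["contraction_rate_pct"], 2) == 8.51
        r = rates(2.25, 7.31, 17.14)
        assert round(r["contraction_rate_pct"], 2) == 29.90

    def test_zero_gain_zero_rate(self):
        assert rates(0.0, 1.0, 9.0)["expansion_rate_pct"] == 0.0

    def test_zero_baseline_raises(self):
        with pytest.raises(ZeroDivisionError):
            rates(1.0, 0.0, 0.0)


class TestTransitions:
    def test_code_formula(self):
        X, _ = transition_code(np.array([[3]]), np.array([[2]]), GridSpec(1, 1), CONST)
        assert X[0, 0] == 32

    def test_no_change_only_diagonal(self):
        g = np.random.default_rng(2).integers(1, 5, (10, 10))
        _, mat = transition_code(g, g, GridSpec(10, 10), CONST)
        off = mat.to_numpy() - np.diag(np.diag(mat.to_numpy()))
        assert off.sum() == 0.0

    def test_half_grid_conversion(self):
        a = np.ones((4, 4), int)
        b = np.ones((4, 4), int)
        b[:2] = 2
        X, mat = transition_code(a, b, GridSpec(4, 4), CONST)
        assert mat.loc["unsuitable", "low"] == 8.0

    @pytest.mark.parametrize("seed", range(3))
    def test_margins_match_per_period_grade_areas(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(1, 5, (12, 12))
        b = rng.integers(1, 5, (12, 12))
        _, mat = transition_code(a, b, GridSpec(12, 12), CONST)
        for g in range(1, 5):
            assert mat.iloc[g - 1].sum() == float((a == g).sum())
            assert mat.iloc[:, g - 1].sum() == float((b == g).sum())

    def test_invalid_codes_raise(self):
        with pytest.raises(ValueError):
            transition_code(np.array([[5]]), np.array([[1]]), GridSpec(1, 1), CONST)


class TestSuitableMask:
    def test_class_modes(self):
        P = np.array([[0.2, 0.5, 0.7, 0.9]])
        assert list(suitable_mask(P, "binary")[0]) == [0, 1, 1, 1]
        assert list(suitable_mask(P, "moderate+high")[0]) == [0, 0, 1, 1]


class TestProfiles:
    def _stack(self, n=10):
        elev = np.tile(np.linspace(0, 1000, n), (n, 1))
        return EnvStack(GridSpec(n, n), [Layer("elev", elev)])

    def test_single_row_grid_one_latitude_bin(self):
        stack = EnvStack(GridSpec(1, 5), [Layer("elev", np.zeros((1, 5)))])
        g = np.full((1, 5), 2)
        df = profiles(g, stack, CONST, axis="latitude", n_bins=4)
        assert (df["low"] > 0).sum() == 1

    def test_low_elevation_niche_modal_bin_below_midpoint(self):
        stack = self._stack(20)
        elev = stack["elev"].values
        g = np.where(elev < 300, 3, 1)  # suitable only at low elevation
        df = profiles(g, stack, CONST, axis="elevation", n_bins=10)
        assert df["moderate"].idxmax() < 5

    def test_missing_elev_layer_raises(self):
        stack = EnvStack(GridSpec(3, 3), [Layer("bio1", np.zeros((3, 3)))])
        with pytest.raises(KeyError):
            profiles(np.ones((3, 3), int), stack, CONST, axis="elevation")

    def test_empty_grade_gives_zero_column(self):
        stack = self._stack(6)
        df = profiles(np.ones((6, 6), int), stack, CONST, axis="longitude", n_bins=3)
        assert (df["high"] == 0).all()
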