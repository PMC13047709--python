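import numpy as np
import pytest

from ensdm.grid import GridSpec
from ensdm.occurrences import (OccurrenceSet, PseudoAbsenceSpec, ThinningSpec,
                               assemble, haversine_km, read_occurrences,
                               sample_pseudo_absences, thin, write_occurrences)
from ensdm.synthetic import gen_stack


def _occ(lon, lat):
    return OccurrenceSet(np.asarray(lon, float), np.asarray(lat, float))


class TestThin:
    def test_two_close_records_reduce_to_one(self):
        # ~0.5 km apart along a meridian
        occ = _occ([100.0, 100.0], [20.0, 20.0045])
        assert len(thin(occ, ThinningSpec(1.0, 0))) == 1

    def test_well_separated_records_all_kept(self):
        occ = _occ([100.0, 100.1, 100.2], [20.0, 20.0, 20.0])  # ~10 km spacing
        assert len(thin(occ, ThinningSpec(1.0, 0))) == 3

    def test_single_record_returned(self):
        occ = _occ([1.0], [2.0])
        assert len(thin(occ, ThinningSpec(1.0, 0))) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_greedy_result_is_maximal_separated_set(self, seed):
        """Pairwise separation > radius, and every dropped point is blocked
        by a kept one (exhaustive brute-force distance oracle)."""
        rng = np.random.default_rng(seed)
        occ = _occ(rng.uniform(0, 3, 40), rng.uniform(0, 3, 40))
        spec = ThinningSpec(radius_km=1.0, seed=seed, distance_mode="euclidean")
        kept = thin(occ, spec)
        # oracle: all pairwise distances among kept exceed the radius
        for i in range(len(kept)):
            d = np.hypot(kept.lon - kept.lon[i], kept.lat - kept.lat[i])
            d[i] = np.inf
            assert d.min() > spec.radius_km
        # maximality: every original point is within radius of some kept point
        for x, y in zip(occ.lon, occ.lat):
            d = np.hypot(kept.lon - x, kept.lat - y)
            assert d.min() <= spec.radius_km

    def test_same_seed_reproduces(self):
        rng = np.random.default_rng(9)
        occ = _occ(rng.uniform(0, 1, 30), rng.uniform(0, 1, 30))
        spec = ThinningSpec(1.0, 4, "euclidean")
        a, b = thin(occ, spec), thin(occ, spec)
        assert np.array_equal(a.lon, b.lon)

    def test_haversine_one_degree_latitude(self):
        assert haversine_km(0, 0, 0, 1) == pytest.approx(6371.0 * np.pi / 180, rel=1e-6)


class TestPseudoAbsences:
    @pytest.fixture(scope="class")
    def stack(self):
        return gen_stack(GridSpec(30, 30), seed=2)

    def test_points_unique_and_not_presence_cells(self, stack):
        pres = _occ([5.5, 10.5], [5.5, 10.5])
        sets = sample_pseudo_absences(stack, pres, PseudoAbsenceSpec(200, 2, seed=1))
        assert len(sets) == 2
        for pa in sets:
            cells = {stack.spec.cell_of(x, y) for x, y in zip(pa.lon, pa.lat)}
            assert len(cells) == 200
            assert stack.spec.cell_of(5.5, 5.5) not in cells

    def test_requesting_all_eligible_cells(self, stack):
        pres = _occ([5.5], [5.5])
        n = stack.n_valid - 1
        pa = sample_pseudo_absences(stack, pres, PseudoAbsenceSpec(n, 1, seed=0))[0]
        assert len(pa) == n

    def test_oversized_request_raises_with_counts(self, stack):
        pres = _occ([5.5], [5.5])
        with pytest.raises(ValueError, match="eligible"):
            sample_pseudo_absences(stack, pres, PseudoAbsenceSpec(10**6, 1, seed=0))

    def test_same_seed_identical_sets(self, stack):
        pres = _occ([5.5], [5.5])
        a = sample_pseudo_absences(stack, pres, PseudoAbsenceSpec(100, 1, seed=3))[0]
        b = sample_pseudo_absences(stack, pres, PseudoAbsenceSpec(100, 1, seed=3))[0]
        assert np.array_equal(a.lon, b.lon) and np.array_equal(a.lat, b.lat)


class TestAssemble:
    @pytest.fixture(scope="class")
    def stack(self):
        return gen_stack(GridSpec(40, 40), seed=4)

    def _presences(self, stack, n, seed=0):
        rng = np.random.default_rng(seed)
        rows, cols = np.nonzero(stack.mask)
        idx = rng.choice(len(rows), n, replace=False)
        xs, ys = zip(*(stack.spec.cell_centre(r, c) for r, c in zip(rows[idx], cols[idx])))
        return _occ(xs, ys)

    def test_protocol_weighting_59_presences_1000_absences(self, stack):
        """59 presences vs 1000 pseudo-absences at prevalence 0.5: each PA
        weighs 0.059 and the class weight totals are equal."""
        pres = self._presences(stack, 59)
        pas = sample_pseudo_absences(stack, pres, PseudoAbsenceSpec(1000, 1, seed=1))
        ds = assemble(stack, pres, pas, prevalence=0.5, n_reps=2, seed=0)[0]
        assert ds.w[ds.y == 0][0] == pytest.approx(0.059)
        assert ds.w[ds.y == 1].sum() == pytest.approx(59.0)
        assert ds.w[ds.y == 0].sum() == pytest.approx(ds.w[ds.y == 1].sum())

    def test_equal_counts_all_weights_one(self, stack):
        pres = self._presences(stack, 50)
        pas = sample_pseudo_absences(stack, pres, PseudoAbsenceSpec(50, 1, seed=1))
        ds = assemble(stack, pres, pas, n_reps=1, seed=0)[0]
        assert np.allclose(ds.w, 1.0)

    @pytest.mark.parametrize("n_pres,n_pa,prev", [(37, 211, 0.5), (8, 400, 0.5),
                                                  (120, 75, 0.5)])
    def test_weight_conservation_any_counts(self, stack, n_pres, n_pa, prev):
        pres = self._presences(stack, n_pres, seed=n_pres)
        pas = sample_pseudo_absences(stack, pres, PseudoAbsenceSpec(n_pa, 1, seed=2))
        ds = assemble(stack, pres, pas, prevalence=prev, n_reps=1, seed=0)[0]
        assert ds.w[ds.y == 1].sum() == pytest.approx(ds.w[ds.y == 0].sum())

    def test_split_counts_eight_presences(self, stack):
        """8 presences at train_frac 0.75 -> 6 train / 2 test in every repetition."""
        pres = self._presences(stack, 8)
        pas = sample_pseudo_absences(stack, pres, PseudoAbsenceSpec(40, 1, seed=1))
        ds = assemble(stack, pres, pas, n_reps=10, seed=0)[0]
        for rep in range(10):
            tr, te = ds.fold(rep)
            assert (tr & (ds.y == 1)).sum() == 6
            assert (te & (ds.y == 1)).sum() == 2
            assert (tr & (ds.y == 0)).sum() == 30

    def test_split_reproducible_with_seed(self, stack):
        pres = self._presences(stack, 20)
        pas = sample_pseudo_absences(stack, pres, PseudoAbsenceSpec(60, 1, seed=1))
        a = assemble(stack, pres, pas, n_reps=3, seed=42)[0]
        b = assemble(stack, pres, pas, n_reps=3, seed=42)[0]
        for ra, rb in zip(a.rep_assignments, b.rep_assignments):
            assert np.array_equal(ra, rb)

    def test_too_few_presences_raises(self, stack):
        pres = self._presences(stack, 3)
        pas = sample_pseudo_absences(stack, pres, PseudoAbsenceSpec(10, 1, seed=1))
        with pytest.raises(ValueError, match="presences"):
            assemble(stack, pres, pas, n_reps=1, seed=0)


class TestCSV:
    def test_round_trip(self, tmp_path):
        occ = OccurrenceSet(np.array([1.5, 2.5]), np.array([3.5, 4.5]), "sp")
        p = tmp_path / "occ.csv"
        write_occurrences(occ, p)
        back = read_occurrences(p)
        assert back.species == "sp"
        assert np.allclose(back.lon, occ.lon)

    def test_non_numeric_rows_dropped(self, tmp_path):
        p = tmp_path / "occ.csv"
        p.write_text("species,longitude,latitude\nsp,1.0,2.0\nsp,,3.0\nsp,x,4.0\n")
        assert len(read_occurrences(p)) == 1
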