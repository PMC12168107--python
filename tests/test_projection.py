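import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bioregionet import projection as pj
from bioregionet.grid import make_grid
from bioregionet.synthetic import EnvField


def field(grid, values, variable="temperature"):
    return EnvField(variable, 200, values, np.ones(grid.n_cells, bool), grid)


@pytest.fixture()
def grid():
    return make_grid(-20, 20, -70, -40, 1.0)


class TestDeltaCorrection:
    def test_per_cell_arithmetic(self, grid):
        base = field(grid, np.full(grid.n_cells, 5.0))
        hist = field(grid, np.full(grid.n_cells, 4.2))
        fut = field(grid, np.full(grid.n_cells, 6.2))
        out = pj.delta_correct(base, hist, fut)
        np.testing.assert_allclose(out.values, 7.0)

    def test_zero_anomaly_is_identity(self, grid, rng):
        base = field(grid, rng.normal(10, 3, grid.n_cells))
        hist = field(grid, rng.normal(8, 3, grid.n_cells))
        out = pj.delta_correct(base, hist, hist)
        np.testing.assert_allclose(out.values, base.values)

    def test_uniform_anomaly_shifts_baseline_everywhere(self, grid, rng):
        base = field(grid, rng.normal(10, 3, grid.n_cells))
        hist = field(grid, rng.normal(8, 1, grid.n_cells))
        fut = field(grid, hist.values + 2.0)
        out = pj.delta_correct(base, hist, fut)
        np.testing.assert_allclose(out.values, base.values + 2.0)

    def test_correction_preserves_baseline_spatial_anomalies(self, grid, rng):
        # corrected - baseline equals exactly the GCM anomaly field
        base = field(grid, rng.normal(10, 3, grid.n_cells))
        hist = field(grid, rng.normal(8, 1, grid.n_cells))
        fut = field(grid, hist.values + rng.normal(2, 0.5, grid.n_cells))
        out = pj.delta_correct(base, hist, fut)
        np.testing.assert_allclose(out.values - base.values, fut.values - hist.values)

    def test_grid_mismatch_rejected(self, grid):
        other = make_grid(-20, 20, -60, -40, 1.0)
        base = field(grid, np.zeros(grid.n_cells))
        h = field(other, np.zeros(other.n_cells))
        with pytest.raises(ValueError, match="grid"):
            pj.delta_correct(base, h, h)


class _ConstMember:
    def __init__(self, value, region_id=1, accepted=True):
        self.value = value
        self.region_id = region_id
        self.accepted = accepted
        self.technique, self.fold = "const", 1

    def predict(self, X):
        return np.full(len(X), self.value)


class TestProjectAndClassify:
    def test_mean_and_sd_over_members(self, grid):
        stack = {"t": field(grid, np.zeros(grid.n_cells))}
        cells = np.arange(10)
        pred = pj.project([_ConstMember(0.2), _ConstMember(0.4)], stack, cells)
        np.testing.assert_allclose(pred.mean, 0.3)
        np.testing.assert_allclose(pred.sd, 0.1)

    def test_identical_members_have_zero_sd(self, grid):
        stack = {"t": field(grid, np.zeros(grid.n_cells))}
        pred = pj.project([_ConstMember(0.7)] * 3, stack, np.arange(5))
        np.testing.assert_allclose(pred.sd, 0.0, atol=1e-12)

    def test_member_times_gcm_run_count(self, grid):
        stacks = [{"t": field(grid, np.zeros(grid.n_cells))} for _ in range(10)]
        members = [_ConstMember(0.5) for _ in range(20)]
        pred = pj.project(members, stacks, np.arange(4))
        assert pred.n_runs == 200

    def test_rejected_members_excluded(self, grid):
        stack = {"t": field(grid, np.zeros(grid.n_cells))}
        members = [_ConstMember(0.2, accepted=True), _ConstMember(0.9, accepted=False)]
        pred = pj.project(members, stack, np.arange(3))
        assert pred.n_runs == 1
        with pytest.raises(ValueError, match="accepted"):
            pj.project([_ConstMember(0.9, accepted=False)], stack, np.arange(3))

    @pytest.mark.parametrize(
        "p1,p2,winner,conf",
        [((0.9, 0.2), None, 1, 0.9), ((0.2, 0.6), None, 2, 0.6)],
    )
    def test_argmax_classification(self, p1, p2, winner, conf):
        cells = np.arange(1)
        a = pj.EnsemblePrediction(1, cells, np.array([[p1[0]]]), ["m"])
        b = pj.EnsemblePrediction(2, cells, np.array([[p1[1]]]), ["m"])
        hm = pj.classify_cells([a, b])
        assert hm.region[0] == winner and hm.confidence[0] == pytest.approx(conf)

    def test_exact_tie_flagged_as_transition(self):
        cells = np.arange(1)
        a = pj.EnsemblePrediction(1, cells, np.array([[0.5]]), ["m"])
        b = pj.EnsemblePrediction(2, cells, np.array([[0.5]]), ["m"])
        hm = pj.classify_cells([a, b])
        assert hm.tie[0] and hm.region[0] == -1

    def test_single_region_rejected(self):
        a = pj.EnsemblePrediction(1, np.arange(1), np.array([[0.5]]), ["m"])
        with pytest.raises(ValueError):
            pj.classify_cells([a])


class TestTransitionIndex:
    def test_equal_shares_attain_maximum(self):
        assert pj.transition_index(np.array([0.5, 0.5])) == pytest.approx(1.0, abs=1e-12)
        assert pj.transition_index(np.array([0.2, 0.2, 0.2])) == pytest.approx(1.0, abs=1e-12)

    def test_single_nonzero_share_gives_zero(self):
        assert pj.transition_index(np.array([0.3, 0.0])) == pytest.approx(0.0, abs=1e-12)

    def test_spot_value_matches_independent_entropy(self):
        # -(0.8 ln 0.8 + 0.2 ln 0.2) / ln 2, computed independently
        expected = -(0.8 * np.log(0.8) + 0.2 * np.log(0.2)) / np.log(2)
        assert pj.transition_index(np.array([0.8, 0.2])) == pytest.approx(expected, abs=1e-9)
        assert pj.transition_index(np.array([0.8, 0.2])) == pytest.approx(0.7219280948, abs=1e-9)

    def test_all_zero_is_undefined(self):
        assert np.isnan(pj.transition_index(np.array([0.0, 0.0])))

    def test_negative_probability_rejected(self):
        with pytest.raises(ValueError):
            pj.transition_index(np.array([-0.1, 0.5]))

    def test_fewer_than_two_regions_rejected(self):
        with pytest.raises(ValueError):
            pj.transition_index(np.array([[1.0]]))

    @settings(deadline=None, max_examples=200)
    @given(
        p=st.tuples(st.floats(0.01, 1), st.floats(0.01, 1), st.floats(0, 1)),
        c=st.floats(0.01, 100),
    )
    def test_scale_invariance_and_bounds(self, p, c):
        arr = np.array(p)
        ti = pj.transition_index(arr)
        assert -1e-12 <= ti <= 1 + 1e-12
        assert pj.transition_index(c * arr) == pytest.approx(ti, abs=1e-9)

    def test_simplex_sweep_maximum_only_at_equal_shares(self):
        g = np.linspace(0, 1, 201)
        p1, p2 = np.meshgrid(g, g)
        pv = np.column_stack([p1.ravel(), p2.ravel()])
        pv = pv[pv.sum(axis=1) > 0]
        ti = pj.transition_index(pv)
        assert ti.max() == pytest.approx(1.0, abs=1e-12)
        at_max = pv[ti > 1 - 1e-9]
        np.testing.assert_allclose(at_max[:, 0], at_max[:, 1], rtol=1e-9)


class TestCellAreas:
    def test_equatorial_one_degree_cell(self):
        grid = make_grid(-180, 180, -2, 2, 1.0)
        areas = pj.cell_areas(grid)
        bottom, _ = grid.cell_lat_bounds()
        eq = areas[np.isclose(bottom, 0.0)]
        r = 6371.0
        expected = r**2 * np.deg2rad(1.0) * np.sin(np.deg2rad(1.0))
        np.testing.assert_allclose(eq, expected)
        assert expected == pytest.approx(12364, rel=1e-3)

    def test_latitude_band_sums_to_closed_form(self):
        grid = make_grid(-180, 180, -60, -50, 1.0)
        areas = pj.cell_areas(grid)
        r = 6371.0
        expected = 2 * np.pi * r**2 * (np.sin(np.deg2rad(-50)) - np.sin(np.deg2rad(-60)))
        assert areas.sum() == pytest.approx(expected, rel=1e-12)

    def test_areas_shrink_poleward(self):
        grid = make_grid(-180, 180, -75, -30, 1.0)
        areas = pj.cell_areas(grid).reshape(grid.n_lat, grid.n_lon)
        assert np.all(np.diff(areas[:, 0]) > 0)  # southward rows smaller

    def test_full_sphere_sums_to_4_pi_r_squared(self):
        grid = make_grid(-180, 180, -90, 90, 1.0)
        total = pj.cell_areas(grid).sum()
        assert total == pytest.approx(4 * np.pi * 6371.0**2, rel=1e-6)


class TestAreaChange:
    def _pred(self, runs, region=1):
        runs = np.asarray(runs, dtype=float)
        return pj.EnsemblePrediction(region, np.arange(runs.shape[1]), runs, [f"r{i}" for i in range(runs.shape[0])])

    def test_identical_futures_give_zero_change_nowhere_significant(self, rng):
        runs = rng.random((5, 40))
        areas = np.ones(40)
        tab = pj.area_change(self._pred(runs), self._pred(runs), areas)
        np.testing.assert_allclose(tab["delta_area_km2"], 0.0)
        assert not tab["significant"].any()

    def test_single_covering_class_reduces_to_total_area_difference(self, rng):
        pres = rng.random((4, 30))
        fut = rng.random((8, 30))
        areas = rng.uniform(1, 2, 30)
        tab = pj.area_change(self._pred(pres), self._pred(fut), areas, classes=((0.0, 1.0),))
        # every probability lies in the single class -> delta must be 0
        assert tab["delta_area_km2"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_classes_partition_probability_space(self, rng):
        pres = rng.random((4, 50))
        areas = np.ones(50)
        per_run = np.zeros(4)
        for lo, hi in pj.PROBABILITY_CLASSES:
            inside = (pres > lo) & (pres <= hi) if lo > 0 else pres <= hi
            per_run += inside.sum(axis=1)
        np.testing.assert_allclose(per_run, 50)

    def test_systematic_shift_detected_as_significant(self, rng):
        pres = np.clip(rng.normal(0.3, 0.05, (10, 60)), 0, 1)
        fut = np.clip(np.tile(pres, (5, 1)) + 0.4 + rng.normal(0, 0.01, (50, 60)), 0, 1)
        tab = pj.area_change(self._pred(pres), self._pred(fut), np.ones(60))
        high = tab[tab["class"] == "very_high"].iloc[0]
        low = tab[tab["class"] == "low"].iloc[0]
        assert low["delta_area_km2"] < 0 < high["delta_area_km2"]
        assert high["significant"]

    def test_too_few_runs_reported_untested(self, rng):
        pres = rng.random((1, 20))
        fut = rng.random((2, 20))
        tab = pj.area_change(self._pred(pres), self._pred(fut), np.ones(20))
        assert (tab["test"] == "none").all()


class TestTransitionZoneChange:
    def test_identical_maps_no_change(self, grid, rng):
        ti = rng.random(grid.n_cells)
        cells = np.arange(grid.n_cells)
        tab = pj.transition_zone_change(ti, ti, np.ones(grid.n_cells), cells, grid, sector_deg=20.0)
        np.testing.assert_allclose(tab["delta_area_km2"], 0.0)

    def test_zero_threshold_includes_every_defined_cell(self, grid, rng):
        ti = rng.random(grid.n_cells)
        cells = np.arange(grid.n_cells)
        areas = pj.cell_areas(grid)
        tab = pj.transition_zone_change(ti, ti, areas, cells, grid, ti_threshold=0.0, sector_deg=40.0)
        assert tab["area_present_km2"].sum() == pytest.approx(areas.sum(), rel=1e-9)

    def test_poleward_isotherm_shift_contracts_the_zone(self):
        # a zonal band of high TI moved poleward covers less area because
        # spherical cells shrink toward the pole
        grid = make_grid(-180, 180, -75, -30, 1.0)
        _, lat = grid.cell_centers()
        ti_p = ((lat > -56) & (lat < -52)).astype(float)
        ti_f = ((lat > -66) & (lat < -62)).astype(float)
        areas = pj.cell_areas(grid)
        cells = np.arange(grid.n_cells)
        tab = pj.transition_zone_change(ti_p, ti_f, areas, cells, grid, ti_threshold=0.5)
        assert tab["delta_area_km2"].sum() < 0
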