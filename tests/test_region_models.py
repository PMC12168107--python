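import numpy as np
import pandas as pd
import pytest

from bioregionet import region_models as rm
from bioregionet.bionet import RegionAssignment
from bioregionet.grid import make_grid
from bioregionet.synthetic import EnvField


def make_assignment(cell_regions: dict[int, int]) -> RegionAssignment:
    cells = pd.Index(sorted(cell_regions), name="cell_id")
    series = pd.Series([cell_regions[c] for c in cells], index=cells, name="region")
    sizes = series[series > 0].value_counts().to_dict()
    return RegionAssignment({}, pd.Series(dtype=int), series, {r: int(n) for r, n in sizes.items()}, 20)


def stack_for(grid, **fields):
    return {
        name: EnvField(name.split("_")[0], 200, vals, np.ones(grid.n_cells, bool), grid)
        for name, vals in fields.items()
    }


@pytest.fixture()
def grid():
    return make_grid(-20, 20, -70, -40, 1.0)


class TestBuildPA:
    def test_presences_and_absences_from_region_membership(self, grid):
        regions = {c: 1 for c in range(200)}
        regions.update({c + 200: 2 for c in range(150)})
        asn = make_assignment(regions)
        stack = stack_for(grid, temperature_200=np.linspace(0, 10, grid.n_cells))
        ds = rm.build_pa(asn, 1, stack)
        assert ds.n_presences == 200 and len(ds.y) == 350
        assert ds.modellable

    def test_region_below_presence_threshold_flagged_unmodellable(self, grid):
        regions = {c: 1 for c in range(12)}
        regions.update({c + 20: 2 for c in range(100)})
        asn = make_assignment(regions)
        stack = stack_for(grid, temperature_200=np.linspace(0, 10, grid.n_cells))
        ds = rm.build_pa(asn, 1, stack)
        assert not ds.modellable

    def test_unassigned_cells_never_used_as_absences(self, grid):
        regions = {c: 1 for c in range(50)}
        regions.update({c + 50: 2 for c in range(40)})
        regions.update({c + 100: 0 for c in range(30)})  # minor-cluster cells
        asn = make_assignment(regions)
        stack = stack_for(grid, temperature_200=np.linspace(0, 10, grid.n_cells))
        ds = rm.build_pa(asn, 1, stack)
        assert len(ds.y) == 90
        assert set(ds.cells) == set(range(90))

    def test_unretained_region_rejected(self, grid):
        asn = make_assignment({c: 1 for c in range(40)})
        stack = stack_for(grid, temperature_200=np.zeros(grid.n_cells))
        with pytest.raises(ValueError, match="not retained"):
            rm.build_pa(asn, 9, stack)


class TestCollinearityGroups:
    def test_correlated_pair_grouped_independent_variable_alone(self, rng):
        t0 = rng.normal(size=400)
        x = pd.DataFrame({
            "T0": t0,
            "T100": t0 + rng.normal(0, 0.1, 400),   # rho ~ 0.99
            "salinity": rng.normal(size=400),       # independent
        })
        groups = rm.collinearity_groups(x, rho=0.7)
        assert sorted(map(sorted, groups)) == [["T0", "T100"], ["salinity"]]

    def test_all_weakly_correlated_stay_separate(self, rng):
        x = pd.DataFrame(rng.normal(size=(300, 4)), columns=list("abcd"))
        groups = rm.collinearity_groups(x, rho=0.7)
        assert len(groups) == 4

    def test_chain_forms_one_transitive_component(self, rng):
        a = rng.normal(size=500)
        b = 0.9 * a + rng.normal(0, 0.44, 500)      # rho(a,b) ~ 0.9
        c = 0.9 * b + rng.normal(0, 0.44, 500)      # rho(b,c) ~ 0.9, rho(a,c) lower
        x = pd.DataFrame({"A": a, "B": b, "C": c})
        groups = rm.collinearity_groups(x, rho=0.85)
        assert sorted(map(sorted, groups)) == [["A", "B", "C"]]

    def test_constant_variable_excluded_with_warning(self, rng):
        x = pd.DataFrame({"a": rng.normal(size=100), "flat": np.ones(100)})
        with pytest.warns(UserWarning, match="constant"):
            groups = rm.collinearity_groups(x)
        assert [g for g in groups] == [["a"]]


class TestPermutationImportance:
    def _fit(self, X, y, technique="glm", seed=0):
        model = rm.TECHNIQUES[technique](seed=seed).fit(X, y)
        return rm.FittedMember(technique, -1, model, 1)

    def test_uninformative_variable_has_near_zero_importance(self, rng):
        x = pd.DataFrame({"t": rng.normal(size=800), "noise": rng.normal(size=800)})
        y = (x["t"] > 0).astype(int).to_numpy()
        m = self._fit(x, y)
        rec = rm.permutation_importance(m, x, "noise", seed=1)
        assert rec["importance"] < 0.05

    def test_single_strong_predictor_has_high_importance(self, rng):
        x = pd.DataFrame({"t": rng.normal(size=800)})
        y = (x["t"] > 0).astype(int).to_numpy()
        m = self._fit(x, y)
        rec = rm.permutation_importance(m, x, "t", seed=1)
        assert rec["importance"] > 0.8

    def test_same_seed_gives_identical_importance(self, rng):
        x = pd.DataFrame({"t": rng.normal(size=300), "u": rng.normal(size=300)})
        y = (x["t"] + 0.3 * x["u"] > 0).astype(int).to_numpy()
        m = self._fit(x, y)
        a = rm.permutation_importance(m, x, "t", seed=7)
        b = rm.permutation_importance(m, x, "t", seed=7)
        assert a["importance"] == b["importance"]


class TestSelectVariables:
    def test_only_informative_variable_survives(self, rng):
        n = 1200
        t = rng.normal(size=n)
        x = pd.DataFrame({
            "temperature_200": t,
            "temperature_0": t + rng.normal(0, 0.05, n),  # collinear clone
            "salinity_200": rng.normal(size=n),
            "oxygen_200": rng.normal(size=n),
        })
        y = (t > 0).astype(int)
        ds = rm.PADataset(1, np.arange(n), y, x)
        selected, imp = rm.select_variables(ds, technique_names=("glm", "fda"), seed=0)
        assert len(selected) == 1 and selected[0].startswith("temperature")
        med = imp.groupby("variable")["importance"].median()
        assert med[selected[0]] > 0.10

    def test_pure_noise_stack_is_rejected_with_diagnostic(self, rng):
        n = 400
        x = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        y = rng.integers(0, 2, n)
        ds = rm.PADataset(1, np.arange(n), y, x)
        with pytest.raises(ValueError, match="cannot be modelled"):
            rm.select_variables(ds, technique_names=("glm", "fda"), seed=0)


class TestBlocksAndFolds:
    def test_blocks_tile_the_grid(self, grid):
        blocks = rm.spatial_blocks(grid, 10.0)
        lon, lat = grid.cell_centers()
        assert blocks.shape == (grid.n_cells,)
        # cells 10 degrees apart in lon on the same row differ in block
        assert blocks[0] != blocks[10]
        assert len(np.unique(blocks)) == 4 * 3

    def test_block_smaller_than_resolution_rejected(self, grid):
        with pytest.raises(ValueError):
            rm.spatial_blocks(grid, 0.5)

    def test_eight_blocks_give_two_per_fold(self, grid, rng):
        ds = rm.PADataset(
            1, np.arange(grid.n_cells),
            rng.integers(0, 2, grid.n_cells),
            pd.DataFrame({"t": rng.normal(size=grid.n_cells)}),
        )
        blocks = rm.spatial_blocks(grid, 10.0)[: grid.n_cells]
        blocks = blocks % 8
        folds = rm.assign_folds(ds, blocks, k=4, seed=0)
        per_fold = pd.crosstab(folds.cell_block, folds.cell_fold)
        counts = folds.cell_fold.groupby(folds.cell_block.values).first().value_counts()
        assert sorted(counts.tolist()) == [2, 2, 2, 2]

    def test_fold_balance_within_tolerance(self, grid, rng):
        y = rng.integers(0, 2, grid.n_cells)
        ds = rm.PADataset(1, np.arange(grid.n_cells), y, pd.DataFrame({"t": rng.normal(size=grid.n_cells)}))
        folds = rm.assign_folds(ds, rm.spatial_blocks(grid, 5.0), k=4, seed=0, tol=0.1)
        assert folds.balanced
        for f in range(1, 5):
            share = y[folds.cell_fold.to_numpy() == f].sum() / y.sum()
            assert abs(share - 0.25) <= 0.25 * 0.1 + 1e-9

    def test_degenerate_concentration_warns(self, grid, rng):
        y = np.zeros(grid.n_cells, int)
        y[:30] = 1  # all presences in one corner block
        ds = rm.PADataset(1, np.arange(grid.n_cells), y, pd.DataFrame({"t": rng.normal(size=grid.n_cells)}))
        with pytest.warns(UserWarning, match="balance"):
            folds = rm.assign_folds(ds, rm.spatial_blocks(grid, 30.0), k=4, seed=0, max_retries=50)
        assert not folds.balanced

    def test_same_seed_same_folds(self, grid, rng):
        y = rng.integers(0, 2, grid.n_cells)
        ds = rm.PADataset(1, np.arange(grid.n_cells), y, pd.DataFrame({"t": rng.normal(size=grid.n_cells)}))
        blocks = rm.spatial_blocks(grid, 5.0)
        a = rm.assign_folds(ds, blocks, k=4, seed=3)
        b = rm.assign_folds(ds, blocks, k=4, seed=3)
        assert a.cell_fold.equals(b.cell_fold)

    def test_morans_correlogram_decays_for_gradient_field(self, grid):
        lon, lat = grid.cell_centers()
        cor = rm.morans_correlogram(grid, lat.astype(float), lag_step=2.0, seed=0)
        assert cor["morans_i"].iloc[0] > 0.5
        assert cor["morans_i"].iloc[-1] < cor["morans_i"].iloc[0]
        size = rm.auto_block_size(grid, lat.astype(float), seed=0)
        assert size >= grid.resolution


class TestFitAndEvaluate:
    def _dataset(self, rng, n=600):
        t = np.linspace(-3, 3, n) + rng.normal(0, 0.1, n)
        y = (t > 0).astype(int)
        return rm.PADataset(1, np.arange(n), y, pd.DataFrame({"t": t}))

    def test_two_techniques_four_folds_give_eight_members(self, rng):
        ds = self._dataset(rng)
        folds = rm.assign_folds(ds, np.arange(len(ds.y)) // 40, k=4, seed=0)
        members, failures = rm.fit_region_models(ds, folds, ("glm", "fda"), seed=0)
        assert len(members) == 8 and failures == []

    def test_unmodellable_dataset_rejected(self, rng):
        ds = self._dataset(rng, n=40)
        ds.modellable = False
        with pytest.raises(ValueError, match="cannot be modelled"):
            rm.fit_region_models(ds, None)

    def test_perfectly_separable_data_scores_perfectly(self, rng):
        ds = self._dataset(rng)
        folds = rm.assign_folds(ds, np.arange(len(ds.y)) // 40, k=4, seed=0)
        members, _ = rm.fit_region_models(ds, folds, ("glm",), seed=0)
        ev = rm.evaluate_models(members, ds, folds)
        assert (ev["jaccard"] > 0.9).all()
        assert (ev["auc"] > 0.99).all()
        assert ev["accepted"].all()

    def test_random_predictions_fail_the_jaccard_rule(self, rng):
        # Bernoulli(0.5) predictions binarized at 0.5 on balanced data:
        # expected J = 1/4 / (1/4 + 1/4 + 1/4) = 1/3 < 0.5 -> rejected
        y = np.tile([0, 1], 2000)
        pred = (rng.random(4000) >= 0.5).astype(int)
        tp = int(((pred == 1) & (y == 1)).sum())
        fp = int(((pred == 1) & (y == 0)).sum())
        fn = int(((pred == 0) & (y == 1)).sum())
        j = rm.jaccard_index(tp, fp, fn)
        assert abs(j - 1 / 3) < 0.05
        assert j < rm.JACCARD_MIN

    def test_jaccard_toy_confusion(self):
        assert rm.jaccard_index(tp=3, fp=1, fn=2) == 0.5

    def test_member_failure_is_recorded_not_raised(self, rng):
        ds = self._dataset(rng)
        folds = rm.assign_folds(ds, np.arange(len(ds.y)) // 40, k=4, seed=0)

        class Exploding(rm._Technique):
            name = "boom"

            def _fit(self, X, y):
                raise RuntimeError("no convergence")

        rm.TECHNIQUES["boom"] = Exploding
        try:
            members, failures = rm.fit_region_models(ds, folds, ("glm", "boom"), seed=0)
        finally:
            del rm.TECHNIQUES["boom"]
        assert len(members) == 4 and len(failures) == 4
        assert failures[0]["error"] == "no convergence"


class TestResponseCurves:
    def test_monotone_response_is_plausible(self, rng):
        n = 500
        t = np.linspace(-3, 3, n)
        y = (t + rng.normal(0, 0.3, n) > 0).astype(int)
        X = pd.DataFrame({"t": t})
        m = rm.FittedMember("glm", 1, rm.TECHNIQUES["glm"]().fit(X, y), 1)
        curves = rm.response_curves([m], X)
        assert curves["plausible"].all()

    def test_oscillating_response_is_flagged(self):
        X = pd.DataFrame({"t": np.linspace(0, 1, 300)})

        class Wiggle(rm._Technique):
            name = "wiggle"

            def _fit(self, X, y):
                pass

            def _predict(self, Z):
                return 0.5 + 0.4 * np.sin(3 * 2 * np.pi * Z[:, 0])

        m = rm.FittedMember("wiggle", 1, Wiggle().fit(X, np.zeros(300, int)), 1)
        curves = rm.response_curves([m], X)
        assert not curves["plausible"].iloc[0]
        assert curves["sign_changes"].iloc[0] >= 3

    def test_region_curves_cross_near_planted_barrier(self, default_run):
        # the two regions' ensemble response to temperature must cross close
        # to the planted 8 degC barrier
        from bioregionet import projection

        scene, reg, proj = default_run["scene"], default_run["reg"], default_run["proj"]
        lab2reg = {v: k for k, v in reg.labels.items()}
        t = scene.t200.values[proj.cells]
        crossing = projection.gradient_crossing(
            proj.present[lab2reg["south"]], proj.present[lab2reg["subtrop"]], t
        )
        assert crossing is not None
        assert abs(crossing - 8.0) <= 1.0
        # both ensembles drop well below their core-range probability there
        near = np.abs(t - crossing) < 0.5
        for r in lab2reg.values():
            core = proj.present[r].mean.max()
            assert proj.present[r].mean[near].mean() < 0.65 < core
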