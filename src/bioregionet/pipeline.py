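"""End-to-end convenience drivers: generate a scene, delineate regions,
model them, and project them under warming.

These wrap the module-level operations in the order a study would run them;
every step remains individually importable. All randomness derives from the
single ``seed`` argument.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bionet, occurrences, projection, region_models, synthetic
from .grid import GridSpec, make_grid

__all__ = ["Scene", "Regionalization", "RegionModelSet", "ProjectionResult",
           "build_scene", "regionalize", "fit_models", "project_warming"]


@dataclass
class Scene:
    grid: GridSpec
    t200: synthetic.EnvField
    env_stack: dict[str, synthetic.EnvField]
    effort: np.ndarray
    pool: list[synthetic.NicheSpec]
    records: pd.DataFrame
    truth: synthetic.TruthTable
    seed: int


def build_scene(
    seed: int = 0,
    grid: GridSpec | None = None,
    n_south: int = 30,
    n_subtrop: int = 30,
    n_widespread: int = 5,
    n_local: int = 4,
    barrier_temp: float = 8.0,
) -> Scene:
    """Default study scene: 1-degree circum-hemispheric grid (16,200 cells),
    two thermal guilds straddling an 8 degC barrier at 200 m, plus widespread
    and localized species, under heterogeneous sampling effort."""
    grid = grid if grid is not None else make_grid()
    ss = np.random.SeedSequence(seed)
    s_field, s_effort, s_pool, s_occ, s_stack = [int(s) for s in ss.generate_state(5) >> 1]
    t200 = synthetic.make_temperature_field(grid, seed=s_field)
    effort = synthetic.make_effort_field(grid, seed=s_effort)
    pool = synthetic.make_species_pool(
        n_south, n_subtrop, n_widespread, n_local, barrier_temp=barrier_temp, seed=s_pool
    )
    records, truth = synthetic.simulate_occurrences(
        pool, t200, effort, seed=s_occ, barrier_temp=barrier_temp
    )
    env_stack = synthetic.make_env_stack(grid, temperature200=t200, seed=s_stack)
    return Scene(grid, t200, env_stack, effort, pool, records, truth, seed)


@dataclass
class Regionalization:
    pm: occurrences.PresenceMatrix
    net: bionet.BipartiteNetwork
    partition: bionet.Partition
    assignment: bionet.RegionAssignment
    labels: dict[int, str]
    fidelity: pd.DataFrame
    clean_report: occurrences.CleanReport


def regionalize(
    scene: Scene,
    n_runs: int = 100,
    min_nodes: int = 20,
    seed: int | None = None,
) -> Regionalization:
    """Clean and rasterize the records, build the bipartite network, cluster
    it by the map equation (best of ``n_runs`` restarts), filter minor
    clusters, and compute species fidelity."""
    seed = scene.seed if seed is None else seed
    rec, report = occurrences.clean_coordinates(scene.records, scene.grid, scene.t200.mask)
    rec, report = occurrences.filter_temporal(rec, report=report)
    summary = occurrences.select_species(rec, scene.grid)
    retained = summary.loc[summary["retained"], "species"].tolist()
    pm = occurrences.rasterize(
        rec, scene.grid, species_subset=retained,
        global_counts=summary.set_index("species")["n_total"],
    )
    net = bionet.build_network(pm)
    partition = bionet.infomap_cluster(net, n_runs=n_runs, seed=seed)
    assignment = bionet.filter_minor_clusters(partition, min_nodes=min_nodes, net=net)
    labels = bionet.label_regions(assignment, scene.t200)
    fidelity = bionet.species_fidelity(partition, pm, net=net, assignment=assignment)
    return Regionalization(pm, net, partition, assignment, labels, fidelity, report)


@dataclass
class RegionModelSet:
    region_id: int
    dataset: region_models.PADataset
    selected: list[str]
    importance: pd.DataFrame
    folds: region_models.FoldAssignment
    members: list[region_models.FittedMember]
    failures: list[dict]
    evaluation: pd.DataFrame


def fit_models(
    scene: Scene,
    reg: Regionalization,
    block_deg: float | str = "auto",
    k: int = 4,
    seed: int | None = None,
) -> dict[int, RegionModelSet]:
    """For each modellable region: variable selection, block CV folds, the
    five-technique ensemble, and its held-out evaluation."""
    seed = scene.seed if seed is None else seed
    if block_deg == "auto":
        block_deg = region_models.auto_block_size(
            scene.grid, scene.t200.values, seed=seed, max_lag=90.0
        )
    blocks = region_models.spatial_blocks(scene.grid, float(block_deg))
    out: dict[int, RegionModelSet] = {}
    for r in reg.assignment.regions:
        ds = region_models.build_pa(reg.assignment, r, scene.env_stack)
        if not ds.modellable:
            out[r] = RegionModelSet(r, ds, [], pd.DataFrame(), None, [], [], pd.DataFrame())
            continue
        selected, imp = region_models.select_variables(ds, seed=seed + r)
        ds_sel = ds.with_variables(selected)
        folds = region_models.assign_folds(ds_sel, blocks, k=k, seed=seed + 31 * r)
        members, failures = region_models.fit_region_models(ds_sel, folds, seed=seed + 131 * r)
        evaluation = region_models.evaluate_models(members, ds_sel, folds)
        out[r] = RegionModelSet(r, ds_sel, selected, imp, folds, members, failures, evaluation)
    return out


@dataclass
class ProjectionResult:
    cells: np.ndarray
    present: dict[int, projection.EnsemblePrediction]
    future: dict[int, projection.EnsemblePrediction]
    hard_present: projection.HardMap
    hard_future: projection.HardMap
    ti_present: np.ndarray
    ti_future: np.ndarray
    areas: np.ndarray
    area_change: pd.DataFrame
    transition_change: pd.DataFrame


def project_warming(
    scene: Scene,
    modelsets: dict[int, RegionModelSet],
    scenario: synthetic.ScenarioSpec | None = None,
) -> ProjectionResult:
    """Delta-correct each pseudo-GCM's fields, project the accepted members
    on baseline and corrected stacks, and derive hard maps, transition-index
    maps and the per-class equal-area change table."""
    scenario = scenario if scenario is not None else synthetic.ScenarioSpec(seed=scene.seed)
    grid = scene.grid
    cells = np.flatnonzero(scene.t200.mask)
    gcm_pairs = synthetic.make_future_anomalies(scene.t200, scenario)
    # corrected future stacks: the warming anomaly applies to every
    # temperature depth; non-thermal variables are held at baseline
    future_stacks = []
    for hist, fut in gcm_pairs:
        corrected_t = projection.delta_correct(scene.t200, hist, fut)
        delta = corrected_t.values - scene.t200.values
        stack = {}
        for name, fld in scene.env_stack.items():
            if fld.variable == "temperature":
                stack[name] = fld.with_values(fld.values + delta)
            else:
                stack[name] = fld
        future_stacks.append(stack)
    modelled = [r for r, ms in modelsets.items() if ms.members]
    present = {
        r: projection.project(modelsets[r].members, scene.env_stack, cells) for r in modelled
    }
    future = {
        r: projection.project(modelsets[r].members, future_stacks, cells) for r in modelled
    }
    hard_p = projection.classify_cells([present[r] for r in modelled])
    hard_f = projection.classify_cells([future[r] for r in modelled])
    ti_p = projection.transition_map([present[r] for r in modelled])
    ti_f = projection.transition_map([future[r] for r in modelled])
    areas = projection.cell_areas(grid)
    tables = [
        projection.area_change(present[r], future[r], areas) for r in modelled
    ]
    tz = projection.transition_zone_change(ti_p, ti_f, areas, cells, grid)
    return ProjectionResult(
        cells, present, future, hard_p, hard_f, ti_p, ti_f, areas,
        pd.concat(tables, ignore_index=True), tz,
    )
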