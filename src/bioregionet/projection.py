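"""Projection of region ensembles under corrected climate fields.

Future climates are built by delta (anomaly) correction - adding each
pseudo-GCM's projected change to the observed baseline rather than using raw
model output. Accepted ensemble members are projected per cell onto the
baseline and onto every corrected field; cells are classified to the region
with the highest mean probability; the transition-zone entropy index
TI = -sum (p_i/P) log(p_i/P), normalized by its simplex maximum log N, maps
where several regions are simultaneously probable; and equal-area gains and
losses are scored per occurrence-probability class with a paired t-test or a
sign test on the per-run area differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grid import GridSpec
from .region_models import FittedMember, env_frame
from .synthetic import EnvField

__all__ = [
    "EnsemblePrediction",
    "HardMap",
    "delta_correct",
    "project",
    "classify_cells",
    "transition_index",
    "transition_map",
    "cell_areas",
    "area_change",
    "transition_zone_change",
    "gradient_crossing",
    "PROBABILITY_CLASSES",
]

EARTH_RADIUS_KM = 6371.0

# Occurrence-probability classes: very low [0, .2], low (.2, .4], moderate
# (.4, .6], high (.6, .8], very high (.8, 1].
PROBABILITY_CLASSES = ((0.0, 0.2), (0.2, 0.4), (0.4, 0.6), (0.6, 0.8), (0.8, 1.0))
CLASS_NAMES = ("very_low", "low", "moderate", "high", "very_high")


def delta_correct(baseline: EnvField, gcm_hist: EnvField, gcm_future: EnvField) -> EnvField:
    """corrected = baseline + (gcm_future - gcm_hist), per cell."""
    for f in (gcm_hist, gcm_future):
        if f.grid != baseline.grid:
            raise ValueError("all fields must share the grid")
    return baseline.with_values(baseline.values + (gcm_future.values - gcm_hist.values))


@dataclass
class EnsemblePrediction:
    """Per-region ensemble of per-cell occurrence probabilities.

    ``runs`` holds every projection (n_runs x n_cells): the fitted members
    for the baseline, members x pseudo-GCMs for a future scenario. ``mean``
    and ``sd`` summarize across runs."""

    region_id: int
    cells: np.ndarray
    runs: np.ndarray
    run_labels: list[str]

    def __post_init__(self):
        self.runs = np.asarray(self.runs, dtype=float)
        if np.nanmin(self.runs) < 0 or np.nanmax(self.runs) > 1:
            raise ValueError("probabilities must lie in [0, 1]")

    @property
    def n_runs(self) -> int:
        return self.runs.shape[0]

    @property
    def mean(self) -> np.ndarray:
        return self.runs.mean(axis=0)

    @property
    def sd(self) -> np.ndarray:
        return self.runs.std(axis=0)


def project(
    members: list[FittedMember],
    env_stacks: list[dict[str, EnvField]] | dict[str, EnvField],
    cells: np.ndarray,
    accepted_only: bool = True,
) -> EnsemblePrediction:
    """Project ensemble members over one env stack (baseline: one run per
    member) or several (future: one run per member x stack/pseudo-GCM)."""
    use = [m for m in members if (m.accepted or not accepted_only)] if accepted_only else members
    if not use:
        raise ValueError("no accepted members to project")
    stacks = [env_stacks] if isinstance(env_stacks, dict) else list(env_stacks)
    runs, labels = [], []
    for g, stack in enumerate(stacks):
        X = env_frame(stack, cells)
        for m in use:
            runs.append(m.predict(X))
            tag = f"{m.technique}_f{m.fold}"
            labels.append(tag if len(stacks) == 1 else f"{tag}_gcm{g}")
    return EnsemblePrediction(use[0].region_id, np.asarray(cells), np.vstack(runs), labels)


@dataclass
class HardMap:
    cells: np.ndarray
    region: np.ndarray  # winning region id; -1 where tied
    confidence: np.ndarray  # winning mean probability
    tie: np.ndarray  # boolean transition flag on exact ties


def classify_cells(predictions: list[EnsemblePrediction]) -> HardMap:
    """Assign every cell to the region with the highest ensemble-mean
    probability; the winning probability is the confidence, and exact ties
    are flagged as transition cells (no region)."""
    if len(predictions) < 2:
        raise ValueError("need predictions for at least 2 regions")
    cells = predictions[0].cells
    for p in predictions[1:]:
        if not np.array_equal(p.cells, cells):
            raise ValueError("predictions must share the cell set")
    means = np.vstack([p.mean for p in predictions])
    ids = np.array([p.region_id for p in predictions])
    order = np.argsort(-means, axis=0)
    win = order[0]
    best = means[win, np.arange(means.shape[1])]
    second = means[order[1], np.arange(means.shape[1])]
    tie = best == second
    region = np.where(tie, -1, ids[win])
    return HardMap(cells, region, best, tie)


def transition_index(p: np.ndarray) -> np.ndarray | float:
    """Normalized entropy of per-region probabilities.

    TI = -sum_i (p_i/P) ln(p_i/P) with P = sum_i p_i and 0 ln 0 := 0,
    normalized by its simplex maximum ln N so that equal shares give 1 and a
    single nonzero share gives 0. Cells with P = 0 return NaN (undefined).
    Accepts one vector (length N) or a matrix (n_cells x N)."""
    arr = np.asarray(p, dtype=float)
    single = arr.ndim == 1
    arr = np.atleast_2d(arr)
    if arr.shape[1] < 2:
        raise ValueError("need at least 2 regions")
    if np.nanmin(arr) < 0:
        raise ValueError("probabilities must be nonnegative")
    total = arr.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        share = arr / total[:, None]
        terms = np.where(share > 0, share * np.log(share), 0.0)
        ti = -terms.sum(axis=1) / np.log(arr.shape[1])
    ti = np.where(total > 0, ti, np.nan)
    return float(ti[0]) if single else ti


def transition_map(predictions: list[EnsemblePrediction]) -> np.ndarray:
    """Per-cell normalized transition index from the regions' ensemble-mean
    probabilities."""
    means = np.column_stack([p.mean for p in predictions])
    return transition_index(means)


def cell_areas(grid: GridSpec, radius_km: float = EARTH_RADIUS_KM) -> np.ndarray:
    """Analytic spherical cell areas, km^2:
    A = R^2 * dlambda * (sin(lat_top) - sin(lat_bottom)). Equal-area exact at
    the sphere level (a latitude band sums to 2 pi R^2 (sin a2 - sin a1))."""
    bottom, top = grid.cell_lat_bounds()
    dlam = np.deg2rad(grid.resolution)
    return radius_km**2 * dlam * (np.sin(np.deg2rad(top)) - np.sin(np.deg2rad(bottom)))


def _class_area_per_run(runs: np.ndarray, areas: np.ndarray, classes) -> np.ndarray:
    """(n_runs x n_classes) total area whose probability falls in each class;
    class intervals are (lo, hi] except the first, which includes 0."""
    out = np.empty((runs.shape[0], len(classes)))
    for ci, (lo, hi) in enumerate(classes):
        inside = (runs > lo) & (runs <= hi) if lo > 0 else (runs >= 0) & (runs <= hi)
        out[:, ci] = inside @ areas
    return out


def area_change(
    present: EnsemblePrediction,
    future: EnsemblePrediction,
    areas: np.ndarray,
    classes=PROBABILITY_CLASSES,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Equal-area gain/loss per occurrence-probability class.

    Each future run (member x pseudo-GCM) is paired with its member's
    baseline run; the per-run area differences are tested per class with a
    paired t-test when Shapiro-Wilk does not reject normality at ``alpha``,
    and a sign test otherwise. With < 3 runs the differences are reported
    untested."""
    if not np.array_equal(present.cells, future.cells):
        raise ValueError("present and future predictions must share the cell set")
    area_cells = np.asarray(areas, dtype=float)[present.cells.astype(int)]
    pres = _class_area_per_run(present.runs, area_cells, classes)
    fut = _class_area_per_run(future.runs, area_cells, classes)
    n_members = present.n_runs
    if future.n_runs % n_members:
        raise ValueError("future runs must be member x GCM blocks of the baseline members")
    reps = future.n_runs // n_members
    pres_rep = np.tile(pres, (reps, 1))
    rows = []
    for ci, ((lo, hi), cname) in enumerate(zip(classes, CLASS_NAMES)):
        diffs = fut[:, ci] - pres_rep[:, ci]
        rec = {
            "region": present.region_id,
            "class": cname,
            "class_lo": lo,
            "class_hi": hi,
            "delta_area_km2": float(np.mean(diffs)),
            "n_runs": diffs.size,
        }
        if diffs.size >= 3:
            spread = np.ptp(diffs) > 0
            normal = bool(stats.shapiro(diffs).pvalue >= alpha) if spread else False
            if normal:
                test, pval = "paired_t", float(stats.ttest_1samp(diffs, 0.0).pvalue)
            else:
                nz = diffs[diffs != 0]
                if nz.size == 0:
                    test, pval = "sign", 1.0
                else:
                    test = "sign"
                    pval = float(stats.binomtest(int((nz > 0).sum()), nz.size, 0.5).pvalue)
            rec.update({"test": test, "p_value": pval, "significant": pval < alpha})
        else:
            rec.update({"test": "none", "p_value": np.nan, "significant": False})
        rows.append(rec)
    return pd.DataFrame(rows)


def gradient_crossing(
    pred_a: EnsemblePrediction,
    pred_b: EnsemblePrediction,
    env_values: np.ndarray,
    bin_width: float = 0.5,
    min_cells: int = 5,
) -> float | None:
    """Gradient value where the two regions' mean occurrence probabilities
    cross: cells are binned along ``env_values`` (e.g., temperature at the
    prediction cells), bin means of each region's ensemble-mean probability
    are differenced, and the first sign change is linearly interpolated.
    Returns None if the curves never cross."""
    env_values = np.asarray(env_values, dtype=float)
    edges = np.arange(np.nanmin(env_values), np.nanmax(env_values) + bin_width, bin_width)
    ib = np.digitize(env_values, edges)
    diff, centers = [], []
    for i in range(1, len(edges)):
        sel = ib == i
        if sel.sum() < min_cells:
            continue
        diff.append(pred_a.mean[sel].mean() - pred_b.mean[sel].mean())
        centers.append(edges[i - 1] + bin_width / 2)
    diff, centers = np.asarray(diff), np.asarray(centers)
    sign_flip = np.where(np.diff(np.sign(diff)))[0]
    if sign_flip.size == 0:
        return None
    i = sign_flip[0]
    x0, x1, y0, y1 = centers[i], centers[i + 1], diff[i], diff[i + 1]
    return float(x0 - y0 * (x1 - x0) / (y1 - y0))


def transition_zone_change(
    ti_present: np.ndarray,
    ti_future: np.ndarray,
    areas: np.ndarray,
    cells: np.ndarray,
    grid: GridSpec,
    ti_threshold: float = 0.9,
    sector_deg: float = 60.0,
) -> pd.DataFrame:
    """Change in transition-zone area (cells with TI_norm >= threshold) per
    longitude sector."""
    if ti_present.shape != ti_future.shape:
        raise ValueError("maps must share the grid")
    cells = np.asarray(cells, dtype=int)
    lon, _ = grid.cell_centers()
    sector = np.floor((lon[cells] - grid.lon_min) / sector_deg).astype(int)
    a = np.asarray(areas, dtype=float)[cells]
    in_p = np.nan_to_num(ti_present) >= ti_threshold
    in_f = np.nan_to_num(ti_future) >= ti_threshold
    rows = []
    for s in np.unique(sector):
        sel = sector == s
        rows.append(
            {
                "sector": int(s),
                "lon_min": grid.lon_min + s * sector_deg,
                "lon_max": grid.lon_min + (s + 1) * sector_deg,
                "area_present_km2": float(a[sel & in_p].sum()),
                "area_future_km2": float(a[sel & in_f].sum()),
                "delta_area_km2": float(a[sel & in_f].sum() - a[sel & in_p].sum()),
            }
        )
    return pd.DataFrame(rows)
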