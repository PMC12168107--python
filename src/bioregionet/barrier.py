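"""Climatic-barrier diagnostics along an environmental gradient.

If two regions' member sites occupy disjoint parts of an environmental
gradient (e.g., temperature at 200 m), the gradient acts as a dispersal
barrier. We quantify the visual "overlap of density curves" criterion as the
overlap coefficient of the two regions' kernel density estimates,
``ovl = integral of min(fA, fB)``, and report the inter-quantile gap between
the 90th percentile of the colder region and the 10th percentile of the
warmer one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bionet import RegionAssignment
from .occurrences import PresenceMatrix
from .synthetic import EnvField

__all__ = [
    "DensityCurve",
    "BarrierReport",
    "species_density_curves",
    "region_env_quantiles",
    "density_overlap",
    "barrier_detect",
]

BANDWIDTH_FLOOR = 0.1  # units of the variable; guards degenerate samples


@dataclass
class DensityCurve:
    subject: str
    variable: str
    depth: float
    support: np.ndarray
    density: np.ndarray

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.support))


def _kde(values: np.ndarray, support: np.ndarray) -> np.ndarray:
    """Gaussian KDE with Silverman bandwidth and a floor for (near-)constant
    samples, evaluated on ``support``."""
    values = np.asarray(values, dtype=float)
    sd = values.std(ddof=1) if values.size > 1 else 0.0
    bw_silverman = 1.06 * sd * values.size ** (-1 / 5) if sd > 0 else 0.0
    bw = max(bw_silverman, BANDWIDTH_FLOOR)
    diff = (support[:, None] - values[None, :]) / bw
    dens = np.exp(-0.5 * diff**2).sum(axis=1) / (values.size * bw * np.sqrt(2 * np.pi))
    return dens


def _support(values: np.ndarray, pad_sd: float = 6.0, n: int = 512) -> np.ndarray:
    # pad covers > 6 bandwidths so edge kernels keep their tail mass and the
    # trapezoid integral stays within 1e-6 of 1 even for degenerate spikes
    sd = max(np.std(values), BANDWIDTH_FLOOR)
    return np.linspace(values.min() - pad_sd * sd, values.max() + pad_sd * sd, n)


def species_density_curves(
    pm: PresenceMatrix, env: EnvField, min_cells: int = 3, n_grid: int = 512
) -> dict[str, DensityCurve]:
    """Per-species density of the environmental values at its presence cells
    (one value per cell). Species with fewer than ``min_cells`` presence
    cells are skipped with a warning."""
    vals_all = env.values[np.asarray(pm.cells, dtype=int)]
    support = _support(vals_all[np.isfinite(vals_all)], n=n_grid)
    out: dict[str, DensityCurve] = {}
    skipped = []
    for i, sp in enumerate(pm.species):
        cols = pm.matrix[i].indices
        vals = vals_all[cols]
        vals = vals[np.isfinite(vals)]
        if vals.size < min_cells:
            skipped.append(sp)
            continue
        out[sp] = DensityCurve(sp, env.variable, env.depth, support, _kde(vals, support))
    if skipped:
        warnings.warn(f"skipped {len(skipped)} species with < {min_cells} presence cells", stacklevel=2)
    return out


def region_env_quantiles(
    assignment: RegionAssignment,
    env: EnvField,
    q: tuple[float, ...] = (0.1, 0.5, 0.9),
    min_cells: int = 10,
) -> pd.DataFrame:
    """Empirical quantiles of the environmental variable over each region's
    member cells; regions with fewer than ``min_cells`` cells are skipped."""
    rows = []
    for r in assignment.regions:
        cells = assignment.cells_of(r).astype(int)
        vals = env.values[cells]
        vals = vals[np.isfinite(vals)]
        if vals.size < min_cells:
            continue
        rows.append(
            {
                "region": r,
                "n_cells": vals.size,
                **{f"q{int(100 * qq)}": float(np.quantile(vals, qq)) for qq in q},
            }
        )
    return pd.DataFrame(rows)


def density_overlap(curve_a: DensityCurve, curve_b: DensityCurve) -> float:
    """Overlap coefficient: integral of the pointwise minimum of the two
    densities over their shared support (1 for identical, 0 for disjoint)."""
    if curve_a.support.shape != curve_b.support.shape or not np.allclose(
        curve_a.support, curve_b.support
    ):
        raise ValueError("curves must share a support grid; resample first")
    return float(np.trapezoid(np.minimum(curve_a.density, curve_b.density), curve_a.support))


@dataclass
class BarrierReport:
    variable: str
    depth: float
    region_cold: int
    region_warm: int
    quantiles: pd.DataFrame
    overlap: float
    overlap_threshold: float
    gap: tuple[float, float] | None
    barrier_supported: bool


def barrier_detect(
    assignment: RegionAssignment,
    env: EnvField,
    overlap_threshold: float = 0.05,
    n_grid: int = 1024,
) -> BarrierReport:
    """Test whether exactly two regions separate along the gradient.

    Builds each region's site-density curve, computes their overlap
    coefficient, and, when overlap falls below the threshold, reports the gap
    interval [90th percentile of the colder region, 10th percentile of the
    warmer region] (when non-empty)."""
    regions = assignment.regions
    if len(regions) != 2:
        raise ValueError("barrier_detect requires exactly 2 regions; call pairwise for more")
    vals = {}
    for r in regions:
        v = env.values[assignment.cells_of(r).astype(int)]
        vals[r] = v[np.isfinite(v)]
    cold, warm = sorted(regions, key=lambda r: np.median(vals[r]))
    allv = np.concatenate(list(vals.values()))
    support = _support(allv, n=n_grid)
    curves = {
        r: DensityCurve(f"region_{r}", env.variable, env.depth, support, _kde(vals[r], support))
        for r in regions
    }
    ovl = density_overlap(curves[cold], curves[warm])
    quant = region_env_quantiles(assignment, env)
    supported = ovl < overlap_threshold
    gap = None
    if supported:
        lo = float(np.quantile(vals[cold], 0.9))
        hi = float(np.quantile(vals[warm], 0.1))
        if lo < hi:
            gap = (lo, hi)
    return BarrierReport(
        variable=env.variable,
        depth=env.depth,
        region_cold=cold,
        region_warm=warm,
        quantiles=quant,
        overlap=ovl,
        overlap_threshold=overlap_threshold,
        gap=gap,
        barrier_supported=supported,
    )
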