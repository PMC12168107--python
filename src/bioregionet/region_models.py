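"""Presence-absence distribution models for the delineated regions.

Each major region is modelled against the others: presences are its member
cells, absences the cells of all other retained regions. Five model families
are fitted per cross-validation fold (linear-logistic, smooth-additive,
neural, discriminant, adaptive-splines), variables are screened for
collinearity (|Spearman rho| > 0.7 groups) and selected by permutation
importance (Imp = 1 - r, median across models > 0.10), and predictive skill
is scored on held-out spatial blocks with the Jaccard index
J = TP / (TP + FP + FN); members with J < 0.5 are rejected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import PolynomialFeatures, StandardScaler
import statsmodels.api as sm
from statsmodels.gam.api import BSplines, GLMGam

from .bionet import RegionAssignment
from .grid import GridSpec
from .synthetic import EnvField

__all__ = [
    "PADataset",
    "FittedMember",
    "env_frame",
    "build_pa",
    "collinearity_groups",
    "choose_representatives",
    "permutation_importance",
    "importance_table",
    "select_variables",
    "morans_correlogram",
    "auto_block_size",
    "spatial_blocks",
    "assign_folds",
    "fit_region_models",
    "evaluate_models",
    "response_curves",
    "jaccard_index",
    "TECHNIQUES",
]

MIN_PRESENCES = 30
JACCARD_MIN = 0.5
IMPORTANCE_MIN = 0.10
IMP_ANTICORR = -0.3


# --------------------------------------------------------------------------
# datasets
# --------------------------------------------------------------------------

def env_frame(env_stack: dict[str, EnvField], cells: np.ndarray) -> pd.DataFrame:
    """Environmental values of the stack at the given cells, one column per
    named variable, indexed by cell id."""
    cells = np.asarray(cells, dtype=int)
    return pd.DataFrame(
        {name: fld.values[cells] for name, fld in env_stack.items()},
        index=pd.Index(cells, name="cell_id"),
    )


@dataclass
class PADataset:
    """Presence-absence table for one region: presences are its cells,
    absences the cells assigned to the other retained regions."""

    region_id: int
    cells: np.ndarray
    y: np.ndarray  # 1 = presence
    X: pd.DataFrame  # env values at cells
    modellable: bool = True

    @property
    def n_presences(self) -> int:
        return int(self.y.sum())

    def with_variables(self, variables: list[str]) -> "PADataset":
        return PADataset(self.region_id, self.cells, self.y, self.X[variables], self.modellable)


def build_pa(
    assignment: RegionAssignment,
    region_id: int,
    env_stack: dict[str, EnvField],
    min_presences: int = MIN_PRESENCES,
) -> PADataset:
    """Frame a region as a presence-absence dataset over assigned cells only;
    unassigned (minor-cluster) cells never appear as absences."""
    cr = assignment.cell_region
    if region_id not in assignment.region_sizes:
        raise ValueError(f"region {region_id} was not retained by the minor-cluster filter")
    cells = cr.index[cr > 0].to_numpy()
    y = (cr[cr > 0] == region_id).to_numpy().astype(int)
    X = env_frame(env_stack, cells)
    ok = np.isfinite(X.to_numpy()).all(axis=1)
    cells, y, X = cells[ok], y[ok], X.loc[ok]
    ds = PADataset(region_id, cells, y, X)
    if ds.n_presences <= min_presences:
        ds.modellable = False
    return ds


# --------------------------------------------------------------------------
# model families
# --------------------------------------------------------------------------


class _Technique:
    """Base wrapper: all families fit on a cell x variable frame and return
    occurrence probabilities; prediction inputs are clamped to the training
    range of each variable (no extrapolation of fitted responses)."""

    name = "base"

    def __init__(self, seed: int = 0):
        self.seed = seed
        self._lo = None
        self._hi = None
        self.columns: list[str] | None = None

    def fit(self, X: pd.DataFrame, y: np.ndarray) -> "_Technique":
        self.columns = list(X.columns)
        arr = X.to_numpy(dtype=float)
        self._lo = arr.min(axis=0)
        self._hi = arr.max(axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            self._fit(arr, np.asarray(y, dtype=int))
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        arr = X[self.columns].to_numpy(dtype=float)
        arr = np.clip(arr, self._lo, self._hi)
        p = self._predict(arr)
        return np.clip(p, 0.0, 1.0)

    def _fit(self, X, y):  # pragma: no cover - abstract
        raise NotImplementedError

    def _predict(self, X):  # pragma: no cover - abstract
        raise NotImplementedError


class LinearLogistic(_Technique):
    """Logistic regression with linear + quadratic terms."""

    name = "glm"

    def _fit(self, X, y):
        self._m = Pipeline(
            [
                ("sc", StandardScaler()),
                ("poly", PolynomialFeatures(degree=2, include_bias=False)),
                ("lr", LogisticRegression(max_iter=2000)),
            ]
        ).fit(X, y)

    def _predict(self, X):
        return self._m.predict_proba(X)[:, 1]


class SmoothAdditive(_Technique):
    """Penalized B-spline additive logistic model (GAM)."""

    name = "gam"

    def __init__(self, seed: int = 0, df: int = 6, alpha: float = 1.0):
        super().__init__(seed)
        self.df = df
        self.alpha = alpha

    def _fit(self, X, y):
        p = X.shape[1]
        self._bs = BSplines(X, df=[self.df] * p, degree=[3] * p)
        model = GLMGam(
            y,
            exog=np.ones((len(y), 1)),
            smoother=self._bs,
            family=sm.families.Binomial(),
            alpha=np.full(p, self.alpha),
        )
        self._res = model.fit()

    def _predict(self, X):
        return np.asarray(
            self._res.predict(exog=np.ones((len(X), 1)), exog_smooth=X)
        )


class NeuralNet(_Technique):
    """Single-hidden-layer perceptron with standardized inputs."""

    name = "ann"

    def _fit(self, X, y):
        self._m = Pipeline(
            [
                ("sc", StandardScaler()),
                (
                    "mlp",
                    MLPClassifier(
                        hidden_layer_sizes=(8,),
                        max_iter=500,
                        random_state=self.seed % 2**31,
                    ),
                ),
            ]
        ).fit(X, y)

    def _predict(self, X):
        return self._m.predict_proba(X)[:, 1]


class Discriminant(_Technique):
    """Discriminant analysis made flexible by a quadratic basis expansion."""

    name = "fda"

    def _fit(self, X, y):
        self._m = Pipeline(
            [
                ("sc", StandardScaler()),
                ("poly", PolynomialFeatures(degree=2, include_bias=False)),
                ("lda", LinearDiscriminantAnalysis()),
            ]
        ).fit(X, y)

    def _predict(self, X):
        return self._m.predict_proba(X)[:, 1]


class AdaptiveSplines(_Technique):
    """Adaptive regression splines: forward selection of hinge-function
    pairs max(x-k, 0) / max(k-x, 0) with knots at training quantiles, fitted
    as a logistic model; greedy additions stop when the training log-loss
    gain falls below ``tol``."""

    name = "mars"

    def __init__(self, seed: int = 0, knot_quantiles=(0.1, 0.3, 0.5, 0.7, 0.9), max_pairs: int = 6, tol: float = 1e-3):
        super().__init__(seed)
        self.knot_quantiles = knot_quantiles
        self.max_pairs = max_pairs
        self.tol = tol

    @staticmethod
    def _hinges(X, var, knot):
        x = X[:, var]
        return np.column_stack([np.maximum(x - knot, 0.0), np.maximum(knot - x, 0.0)])

    def _loss(self, basis, y):
        lr = LogisticRegression(max_iter=1000).fit(basis, y)
        p = np.clip(lr.predict_proba(basis)[:, 1], 1e-12, 1 - 1e-12)
        return -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)), lr

    def _fit(self, X, y):
        n, p = X.shape
        knots = {v: np.unique(np.quantile(X[:, v], self.knot_quantiles)) for v in range(p)}
        candidates = [(v, k) for v in range(p) for k in knots[v]]
        chosen: list[tuple[int, float]] = []
        basis = np.column_stack([X])  # linear terms always included
        best_loss, best_lr = self._loss(basis, y)
        for _ in range(self.max_pairs):
            trial_best = None
            for cand in candidates:
                if cand in chosen:
                    continue
                b = np.hstack([basis, self._hinges(X, *cand)])
                loss, lr = self._loss(b, y)
                if trial_best is None or loss < trial_best[0]:
                    trial_best = (loss, lr, cand, b)
            if trial_best is None or best_loss - trial_best[0] < self.tol:
                break
            best_loss, best_lr, cand, basis = trial_best
            chosen.append(cand)
        self._chosen = chosen
        self._lr = best_lr

    def _transform(self, X):
        cols = [X] + [self._hinges(X, *c) for c in self._chosen]
        return np.hstack(cols)

    def _predict(self, X):
        return self._lr.predict_proba(self._transform(X))[:, 1]


TECHNIQUES: dict[str, type[_Technique]] = {
    "glm": LinearLogistic,
    "gam": SmoothAdditive,
    "ann": NeuralNet,
    "fda": Discriminant,
    "mars": AdaptiveSplines,
}


@dataclass
class FittedMember:
    technique: str
    fold: int
    model: _Technique
    region_id: int
    accepted: bool | None = None

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.model.predict(X)


# --------------------------------------------------------------------------
# variable selection
# --------------------------------------------------------------------------


def collinearity_groups(X: pd.DataFrame, rho: float = 0.7) -> list[list[str]]:
    """Group variables into connected components of the graph joining pairs
    with |Spearman rho| > ``rho``; constant variables are excluded with a
    warning (their rank correlation is undefined)."""
    if X.shape[1] < 2:
        return [[c] for c in X.columns]
    keep = []
    for c in X.columns:
        if np.nanstd(X[c].to_numpy(dtype=float)) == 0:
            warnings.warn(f"excluding constant variable {c!r}", stacklevel=2)
        else:
            keep.append(c)
    if len(keep) < 2:
        return [[c] for c in keep]
    corr = stats.spearmanr(X[keep].to_numpy(dtype=float)).statistic
    if np.ndim(corr) == 0:  # scipy returns a scalar for exactly 2 variables
        corr = np.array([[1.0, corr], [corr, 1.0]])
    n = len(keep)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if abs(corr[i, j]) > rho:
                parent[find(i)] = find(j)
    groups: dict[int, list[str]] = {}
    for i, c in enumerate(keep):
        groups.setdefault(find(i), []).append(c)
    return sorted(groups.values(), key=lambda g: X.columns.get_loc(g[0]))


def permutation_importance(
    member, X: pd.DataFrame, variable: str, n_perm: int = 10, seed: int = 0
) -> dict:
    """Imp = 1 - r, with r the mean Pearson correlation between predictions
    of the fitted model and predictions after shuffling one variable column.
    Zero-variance predictions give Imp = 0 with a warning."""
    rng = np.random.default_rng(seed)
    base = member.predict(X)
    if np.std(base) == 0:
        warnings.warn("zero-variance predictions; importance set to 0", stacklevel=2)
        return {"variable": variable, "r": 1.0, "importance": 0.0}
    rs = []
    Xs = X.copy()
    col = X[variable].to_numpy().copy()
    for _ in range(n_perm):
        Xs[variable] = rng.permutation(col)
        pred = member.predict(Xs)
        if np.std(pred) == 0:
            rs.append(0.0)
        else:
            rs.append(stats.pearsonr(base, pred).statistic)
    r = float(np.mean(rs))
    return {"variable": variable, "r": r, "importance": 1.0 - r}


def _fit_full(y, X, technique_names, seed):
    members = []
    for i, t in enumerate(technique_names):
        try:
            m = TECHNIQUES[t](seed=seed + i).fit(X, y)
            members.append(FittedMember(t, -1, m, -1))
        except Exception as err:  # noqa: BLE001 - a failed fit is data, not a crash
            warnings.warn(f"{t} failed during selection fit: {err}", stacklevel=2)
    return members


def importance_table(members, X: pd.DataFrame, n_perm: int = 10, seed: int = 0) -> pd.DataFrame:
    """Per-variable, per-model permutation importance (long format)."""
    rows = []
    for j, m in enumerate(members):
        for variable in X.columns:
            rec = permutation_importance(m, X, variable, n_perm=n_perm, seed=seed + 97 * j)
            rec["model"] = f"{m.technique}_{m.fold}" if m.fold >= 0 else m.technique
            rows.append(rec)
    return pd.DataFrame(rows)


def choose_representatives(
    y: np.ndarray,
    X: pd.DataFrame,
    groups: list[list[str]],
    techniques: tuple[str, ...] = ("glm", "fda"),
    n_perm: int = 5,
    seed: int = 0,
) -> list[str]:
    """One variable per collinear group: the one with the highest univariate
    median importance over a preliminary round of fast model fits."""
    reps = []
    for g in groups:
        if len(g) == 1:
            reps.append(g[0])
            continue
        scores = {}
        for v in g:
            members = _fit_full(y, X[[v]], techniques, seed)
            imp = importance_table(members, X[[v]], n_perm=n_perm, seed=seed)
            scores[v] = imp["importance"].median()
        reps.append(max(sorted(scores), key=lambda v: scores[v]))
    return reps


def _cv_skill(X: pd.DataFrame, y: np.ndarray, seed: int = 0, k: int = 2) -> float:
    """Out-of-sample association between a reference logistic fit and the
    response: |Pearson r| of k-fold cross-validated probabilities vs y."""
    from sklearn.model_selection import KFold, cross_val_predict

    pipe = Pipeline([("sc", StandardScaler()), ("lr", LogisticRegression(max_iter=1000))])
    cv = KFold(n_splits=k, shuffle=True, random_state=seed % 2**31)
    pred = cross_val_predict(pipe, X.to_numpy(dtype=float), np.asarray(y), cv=cv, method="predict_proba")[:, 1]
    if np.std(pred) == 0 or np.std(y) == 0:
        return 0.0
    return float(abs(stats.pearsonr(pred, np.asarray(y)).statistic))


def select_variables(
    dataset: PADataset,
    rho: float = 0.7,
    importance_min: float = IMPORTANCE_MIN,
    imp_anticorr: float = IMP_ANTICORR,
    technique_names: tuple[str, ...] = ("glm", "gam", "ann", "fda", "mars"),
    n_perm: int = 10,
    seed: int = 0,
) -> tuple[list[str], pd.DataFrame]:
    """Two-stage screen: collinearity grouping with one representative per
    group, then median permutation importance across all model families;
    variables with median Imp > ``importance_min`` are kept. The kept
    variables' per-model importance vectors must not be mutually exclusive
    (pairwise Pearson r < ``imp_anticorr`` raises a diagnostic error)."""
    groups = collinearity_groups(dataset.X, rho=rho)
    reps = choose_representatives(dataset.y, dataset.X, groups, seed=seed)
    Xr = dataset.X[reps]
    members = _fit_full(dataset.y, Xr, technique_names, seed)
    # permutation importance is a contribution share, not a skill measure:
    # near-constant predictions decorrelate under shuffling just as strongly
    # as informative ones, so require some out-of-sample skill before
    # interpreting importances at all
    if _cv_skill(Xr, dataset.y, seed) < 0.1:
        raise ValueError(
            "no informative variables: cross-validated predictions are "
            "uncorrelated with region membership; the region cannot be modelled"
        )
    imp = importance_table(members, Xr, n_perm=n_perm, seed=seed)
    med = imp.groupby("variable")["importance"].median()
    selected = [v for v in reps if med[v] > importance_min]
    if not selected:
        raise ValueError("no variable exceeds the importance threshold; region cannot be modelled")
    if len(selected) > 1:
        wide = imp.pivot(index="model", columns="variable", values="importance")[selected]
        cc = np.corrcoef(wide.to_numpy().T)
        for i in range(len(selected)):
            for j in range(i + 1, len(selected)):
                if cc[i, j] < imp_anticorr:
                    raise ValueError(
                        f"importances of {selected[i]!r} and {selected[j]!r} are negatively "
                        f"correlated (r={cc[i, j]:.2f} < {imp_anticorr}); selection is unstable"
                    )
    return selected, imp


# --------------------------------------------------------------------------
# spatial block cross-validation
# --------------------------------------------------------------------------


def morans_correlogram(
    grid: GridSpec,
    values: np.ndarray,
    lag_step: float = 2.0,
    max_lag: float | None = None,
    n_sample: int = 1500,
    seed: int = 0,
) -> pd.DataFrame:
    """Moran's I of a gridded variable in distance bins (degrees, Euclidean
    on lon/lat with zonal wrap), estimated from a random subsample of cells."""
    rng = np.random.default_rng(seed)
    lon, lat = grid.cell_centers()
    ok = np.flatnonzero(np.isfinite(values))
    if ok.size > n_sample:
        ok = rng.choice(ok, n_sample, replace=False)
    z = values[ok] - values[ok].mean()
    var = (z**2).mean()
    dlon = np.abs(lon[ok][:, None] - lon[ok][None, :])
    dlon = np.minimum(dlon, 360.0 - dlon)
    d = np.hypot(dlon, lat[ok][:, None] - lat[ok][None, :])
    iu = np.triu_indices(ok.size, k=1)
    d = d[iu]
    prod = (z[:, None] * z[None, :])[iu]
    if max_lag is None:
        max_lag = float(d.max())
    bins = np.arange(0.0, max_lag + lag_step, lag_step)
    rows = []
    for lo, hi in zip(bins[:-1], bins[1:]):
        sel = (d >= lo) & (d < hi)
        if sel.sum() < 30:
            continue
        rows.append({"lag": (lo + hi) / 2, "morans_i": float(prod[sel].mean() / var), "n_pairs": int(sel.sum())})
    return pd.DataFrame(rows)


def auto_block_size(
    grid: GridSpec, values: np.ndarray, i_threshold: float = 0.1, seed: int = 0, **kw
) -> float:
    """Block side = the first correlogram lag where Moran's I of the leading
    predictor drops below ``i_threshold`` (fallback: a third of the smaller
    domain side)."""
    cor = morans_correlogram(grid, values, seed=seed, **kw)
    below = cor.loc[cor["morans_i"] < i_threshold, "lag"]
    fallback = min(grid.lon_max - grid.lon_min, grid.lat_max - grid.lat_min) / 3
    size = float(below.iloc[0]) if len(below) else fallback
    return max(size, grid.resolution)


def spatial_blocks(grid: GridSpec, block_deg: float) -> np.ndarray:
    """Contiguous square lon/lat tiles of side ``block_deg``; returns a block
    id per grid cell."""
    if block_deg < grid.resolution:
        raise ValueError("block_deg must be >= grid resolution")
    lon, lat = grid.cell_centers()
    bx = np.floor((lon - grid.lon_min) / block_deg).astype(int)
    by = np.floor((lat - grid.lat_min) / block_deg).astype(int)
    nx = int(np.ceil((grid.lon_max - grid.lon_min) / block_deg))
    return by * nx + bx


@dataclass
class FoldAssignment:
    cell_fold: pd.Series  # cell id -> fold (1..k)
    cell_block: pd.Series
    k: int
    balanced: bool
    max_imbalance: float


def assign_folds(
    dataset: PADataset,
    blocks: np.ndarray,
    k: int = 4,
    seed: int = 0,
    tol: float = 0.1,
    max_retries: int = 1000,
) -> FoldAssignment:
    """Randomly deal blocks to ``k`` folds, retrying until every fold's
    presence and absence counts are within ``tol`` (relative) of n/k; after
    ``max_retries`` the best attempt is returned with a warning."""
    rng = np.random.default_rng(seed)
    cell_block = blocks[np.asarray(dataset.cells, dtype=int)]
    uniq = np.unique(cell_block)
    n_pres, n_abs = dataset.y.sum(), (1 - dataset.y).sum()
    best = None
    for _ in range(max_retries):
        perm = rng.permutation(uniq)
        fold_of_block = {b: (i % k) + 1 for i, b in enumerate(perm)}
        folds = np.array([fold_of_block[b] for b in cell_block])
        dev = 0.0
        for f in range(1, k + 1):
            fp = dataset.y[folds == f].sum()
            fa = (1 - dataset.y)[folds == f].sum()
            dev = max(dev, abs(fp - n_pres / k) / max(n_pres / k, 1), abs(fa - n_abs / k) / max(n_abs / k, 1))
        if best is None or dev < best[0]:
            best = (dev, folds)
        if dev <= tol:
            break
    dev, folds = best
    balanced = dev <= tol
    if not balanced:
        warnings.warn(f"fold balance not attained (max relative deviation {dev:.2f})", stacklevel=2)
    idx = pd.Index(dataset.cells, name="cell_id")
    return FoldAssignment(
        cell_fold=pd.Series(folds, index=idx, name="fold"),
        cell_block=pd.Series(cell_block, index=idx, name="block"),
        k=k,
        balanced=balanced,
        max_imbalance=float(dev),
    )


# --------------------------------------------------------------------------
# fitting and evaluation
# --------------------------------------------------------------------------


def fit_region_models(
    dataset: PADataset,
    folds: FoldAssignment,
    technique_names: tuple[str, ...] = ("glm", "gam", "ann", "fda", "mars"),
    seed: int = 0,
) -> tuple[list[FittedMember], list[dict]]:
    """Fit each technique on the calibration folds of each CV split:
    ``len(technique_names) * k`` ensemble members. Non-convergent members are
    recorded as failures and excluded."""
    if not dataset.modellable:
        raise ValueError(
            f"region {dataset.region_id} has {dataset.n_presences} presences "
            f"(needs > {MIN_PRESENCES}) and cannot be modelled"
        )
    members: list[FittedMember] = []
    failures: list[dict] = []
    fold_arr = folds.cell_fold.to_numpy()
    for f in range(1, folds.k + 1):
        train = fold_arr != f
        Xt, yt = dataset.X.loc[train], dataset.y[train]
        for i, t in enumerate(technique_names):
            try:
                model = TECHNIQUES[t](seed=seed + 13 * f + i).fit(Xt, yt)
                members.append(FittedMember(t, f, model, dataset.region_id))
            except Exception as err:  # noqa: BLE001
                failures.append({"technique": t, "fold": f, "error": str(err)})
    return members, failures


def jaccard_index(tp: int, fp: int, fn: int) -> float:
    """J = TP / (TP + FP + FN): prevalence-independent agreement between
    predicted and observed presences (true negatives do not enter)."""
    denom = tp + fp + fn
    return tp / denom if denom else 0.0


def _jaccard(y_true, y_pred):
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    fp = int(np.sum((y_pred == 1) & (y_true == 0)))
    fn = int(np.sum((y_pred == 0) & (y_true == 1)))
    tn = int(np.sum((y_pred == 0) & (y_true == 0)))
    return tp, fp, fn, tn, jaccard_index(tp, fp, fn)


def _best_threshold(y, p, n_grid: int = 101) -> float:
    grid_t = np.linspace(0.0, 1.0, n_grid)
    js = [(_jaccard(y, (p >= t).astype(int))[4], t) for t in grid_t]
    return max(js)[1]


def evaluate_models(
    members: list[FittedMember],
    dataset: PADataset,
    folds: FoldAssignment,
    jaccard_min: float = JACCARD_MIN,
) -> pd.DataFrame:
    """Score every member on its held-out fold.

    The binarization threshold maximizes J on the member's calibration
    folds; J (threshold-dependent, TN-free) and AUC (threshold-free) are then
    computed on the held-out cells only. Members with J < ``jaccard_min`` are
    rejected; a held-out fold without presences makes the member unevaluable
    and rejected with a reason."""
    fold_arr = folds.cell_fold.to_numpy()
    rows = []
    for m in members:
        hold = fold_arr == m.fold
        train = ~hold
        rec = {"region": dataset.region_id, "technique": m.technique, "fold": m.fold}
        if dataset.y[hold].sum() == 0:
            m.accepted = False
            rec.update({"accepted": False, "reason": "no presences in held-out fold"})
            rows.append(rec)
            continue
        thr = _best_threshold(dataset.y[train], m.predict(dataset.X.loc[train]))
        p_hold = m.predict(dataset.X.loc[hold])
        tp, fp, fn, tn, j = _jaccard(dataset.y[hold], (p_hold >= thr).astype(int))
        auc = float(roc_auc_score(dataset.y[hold], p_hold))
        m.accepted = bool(j >= jaccard_min)
        rec.update(
            {
                "threshold": thr,
                "TP": tp,
                "FP": fp,
                "FN": fn,
                "TN": tn,
                "jaccard": j,
                "auc": auc,
                "accepted": m.accepted,
                "reason": "" if m.accepted else f"J={j:.2f} < {jaccard_min}",
            }
        )
        rows.append(rec)
    return pd.DataFrame(rows)


def response_curves(
    members: list[FittedMember],
    X: pd.DataFrame,
    n_points: int = 100,
    smooth_window: int = 5,
) -> pd.DataFrame:
    """Evaluation-strip response curves: per member and variable, predicted
    probability over the observed value range with the other variables held
    at their medians. A curve is plausible iff, after a moving-average
    smooth, its first difference changes sign at most once (monotone or
    unimodal)."""
    med = X.median()
    rows = []
    for m in members:
        for v in X.columns:
            grid_v = np.linspace(X[v].min(), X[v].max(), n_points)
            strip = pd.DataFrame({c: np.full(n_points, med[c]) for c in X.columns})
            strip[v] = grid_v
            p = m.predict(strip)
            kern = np.ones(smooth_window) / smooth_window
            ps = np.convolve(p, kern, mode="valid")
            diff = np.diff(ps)
            signs = np.sign(diff[np.abs(diff) > 1e-9])
            changes = int(np.sum(signs[1:] != signs[:-1])) if signs.size else 0
            rows.append(
                {
                    "region": m.region_id,
                    "technique": m.technique,
                    "fold": m.fold,
                    "variable": v,
                    "value": grid_v,
                    "probability": p,
                    "sign_changes": changes,
                    "plausible": changes <= 1,
                }
            )
    return pd.DataFrame(rows)
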