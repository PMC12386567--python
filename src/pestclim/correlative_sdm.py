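"""Correlative presence/background distribution modelling.

Covers the statistical track of the pipeline: spatial rarefaction of
occurrence records, pseudo-absence (background) sampling, the 19 standard
bioclimatic predictors computed from monthly climate, a bagged-tree
classifier with stratified k-fold cross-validation, the SDM validation
metrics (AUC, Cohen's kappa, true skill statistic), permutation variable
importance, and natural-breaks (Fisher–Jenks) classification of the
predicted probability surface into four suitability levels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split

from .climate_io import ClimateGrid, GridGeometry, OccurrenceSet

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088  # IUGG mean radius

BIOCLIM_NAMES = tuple(f"bio{i}" for i in range(1, 20))


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km; broadcasts over array inputs."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def rarefy_occurrences(occ: OccurrenceSet, radius_km: float) -> OccurrenceSet:
    """Greedy spatial thinning: keep a record iff no previously kept record
    lies within ``radius_km`` (great-circle). Deterministic in input order;
    the kept set is a maximal subset with pairwise distances > radius.
    """
    if radius_km <= 0:
        raise ValueError("radius_km must be positive")
    kept_lon: list[float] = []
    kept_lat: list[float] = []
    kept_idx: list[int] = []
    for i in range(len(occ)):
        if kept_idx:
            d = haversine_km(occ.lon[i], occ.lat[i], np.array(kept_lon), np.array(kept_lat))
            if (d <= radius_km).any():
                continue
        kept_lon.append(occ.lon[i])
        kept_lat.append(occ.lat[i])
        kept_idx.append(i)
    return OccurrenceSet(
        np.array(kept_lon), np.array(kept_lat), [occ.source[i] for i in kept_idx]
    )


# ---------------------------------------------------------------------------
# Bioclimatic predictors
# ---------------------------------------------------------------------------

def _quarter_sums(x: np.ndarray) -> np.ndarray:
    """Sums over the 12 wrapping 3-month windows; x is (12, ...)."""
    return np.stack([x[m] + x[(m + 1) % 12] + x[(m + 2) % 12] for m in range(12)])


def bioclim_variables(grid: ClimateGrid) -> np.ndarray:
    """The 19 standard bioclimatic summaries, shape (n_rows, n_cols, 19).

    bio1 annual mean temperature, bio2 mean diurnal range, bio3 isothermality,
    bio4 temperature seasonality (sd x 100), bio5/bio6 warmest-month max /
    coldest-month min, bio7 annual range, bio8-bio11 quarter mean temperatures
    (wettest/driest/warmest/coldest quarter), bio12 annual precipitation,
    bio13/bio14 wettest/driest month, bio15 precipitation seasonality (CV),
    bio16-bio19 quarter precipitation. Quarters are any 3 consecutive months
    (wrapping December->January); ties resolved to the earliest quarter.
    """
    shape = grid.geometry.shape
    tmean = (grid.tmin + grid.tmax) / 2.0
    rain = grid.rain
    out = np.empty(shape + (19,), dtype=float)

    out[..., 0] = tmean.mean(axis=0)
    out[..., 1] = (grid.tmax - grid.tmin).mean(axis=0)
    bio5 = grid.tmax.max(axis=0)
    bio6 = grid.tmin.min(axis=0)
    bio7 = bio5 - bio6
    with np.errstate(divide="ignore", invalid="ignore"):
        out[..., 2] = np.where(bio7 > 0, out[..., 1] / np.where(bio7 > 0, bio7, 1.0) * 100.0, 0.0)
    out[..., 3] = tmean.std(axis=0, ddof=1) * 100.0
    out[..., 4] = bio5
    out[..., 5] = bio6
    out[..., 6] = bio7

    q_t = _quarter_sums(tmean) / 3.0
    q_p = _quarter_sums(rain)
    idx_wet = q_p.argmax(axis=0)
    idx_dry = q_p.argmin(axis=0)
    idx_warm = q_t.argmax(axis=0)
    idx_cold = q_t.argmin(axis=0)

    def take(cube, idx):
        return np.take_along_axis(cube, idx[None], axis=0)[0]

    out[..., 7] = take(q_t, idx_wet)
    out[..., 8] = take(q_t, idx_dry)
    out[..., 9] = take(q_t, idx_warm)
    out[..., 10] = take(q_t, idx_cold)
    bio12 = rain.sum(axis=0)
    out[..., 11] = bio12
    out[..., 12] = rain.max(axis=0)
    out[..., 13] = rain.min(axis=0)
    out[..., 14] = 100.0 * rain.std(axis=0, ddof=1) / (1.0 + bio12 / 12.0)
    out[..., 15] = take(q_p, idx_wet)
    out[..., 16] = take(q_p, idx_dry)
    out[..., 17] = take(q_p, idx_warm)
    out[..., 18] = take(q_p, idx_cold)
    return out


# ---------------------------------------------------------------------------
# Training table
# ---------------------------------------------------------------------------

def presence_cells(occ: OccurrenceSet, geometry: GridGeometry) -> np.ndarray:
    """Unique flat indices of land cells containing occurrence records."""
    row, col = geometry.cell_of(occ.lon, occ.lat)
    ok = row >= 0
    flat = row[ok] * geometry.n_cols + col[ok]
    flat = np.unique(flat)
    land = geometry.land_mask.ravel()
    return flat[land[flat]]


def sample_pseudo_absences(
    presences: OccurrenceSet,
    geometry: GridGeometry,
    ratio: int = 4,
    exclusion_km: float = 10.0,
    seed: int = 0,
    n_presence: int | None = None,
) -> np.ndarray:
    """Background cells: uniform draw without replacement from land cells
    farther than ``exclusion_km`` from every presence record. Returns flat
    cell indices; draws ``ratio x n_presence`` of them.
    """
    land_flat = np.flatnonzero(geometry.land_mask.ravel())
    rows, cols = np.divmod(land_flat, geometry.n_cols)
    cell_lon = geometry.lon_centers[cols]
    cell_lat = geometry.lat_centers[rows]
    min_d = np.full(land_flat.size, np.inf)
    for lon, lat in zip(presences.lon, presences.lat):
        min_d = np.minimum(min_d, haversine_km(cell_lon, cell_lat, lon, lat))
    eligible = land_flat[min_d > exclusion_km]
    if n_presence is None:
        n_presence = len(presences)
    n_request = ratio * n_presence
    if eligible.size < n_request:
        raise ValueError(
            f"background pool too small: {eligible.size} eligible cells, "
            f"{n_request} requested"
        )
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(eligible, size=n_request, replace=False))


def build_training_table(
    grid: ClimateGrid,
    occ: OccurrenceSet,
    ratio: int = 4,
    exclusion_km: float = 10.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Presence/background table with bioclim predictors.

    One presence row per occupied cell (records in the same cell collapse);
    ``ratio`` background rows per presence row. Constant predictors are
    dropped with a warning since they carry no information for the fit.
    """
    pres = presence_cells(occ, grid.geometry)
    if pres.size == 0:
        raise ValueError("no occurrence falls on a land cell of the grid")
    bg = sample_pseudo_absences(occ, grid.geometry, ratio, exclusion_km, seed, n_presence=pres.size)
    bio = bioclim_variables(grid).reshape(-1, 19)
    cells = np.concatenate([pres, bg])
    labels = np.concatenate([np.ones(pres.size, dtype=int), np.zeros(bg.size, dtype=int)])
    table = pd.DataFrame(bio[cells], columns=list(BIOCLIM_NAMES))
    table.insert(0, "cell_id", cells)
    table.insert(1, "label", labels)
    constant = [c for c in BIOCLIM_NAMES if table[c].nunique() <= 1]
    if len(constant) == len(BIOCLIM_NAMES):
        raise ValueError("all predictors are constant")
    if constant:
        logger.warning("dropping constant predictors: %s", constant)
        table = table.drop(columns=constant)
    return table


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """AUC/kappa/TSS at a threshold (default: the max-TSS threshold)."""

    auc: float
    kappa: float
    tss: float
    threshold: float
    sensitivity: float
    specificity: float
    per_fold: pd.DataFrame | None = None


def auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the normalized Mann–Whitney U statistic (midranks for ties)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes required")
    ranks = rankdata(scores, method="average")
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def metrics_from_confusion(tp: float, fn: float, tn: float, fp: float) -> dict[str, float]:
    """Kappa and TSS from confusion-matrix counts.

    kappa = (p_o - p_e) / (1 - p_e) with expected agreement p_e from the
    marginals; TSS = sensitivity + specificity - 1.
    """
    n = tp + fn + tn + fp
    sens = tp / (tp + fn) if tp + fn > 0 else 0.0
    spec = tn / (tn + fp) if tn + fp > 0 else 0.0
    po = (tp + tn) / n
    pe = ((tp + fn) * (tp + fp) + (tn + fp) * (tn + fn)) / n**2
    kappa = (po - pe) / (1 - pe) if pe < 1 else 0.0
    return {
        "sensitivity": sens,
        "specificity": spec,
        "tss": sens + spec - 1.0,
        "kappa": kappa,
    }


def max_tss_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Threshold (predict presence when score >= t) maximizing TSS.

    Candidates are the unique scores; among ties the smallest threshold is
    returned, making the choice deterministic.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    order = np.argsort(scores, kind="stable")
    s, y = scores[order], labels[order]
    n1 = y.sum()
    n0 = y.size - n1
    # Predicting positive for score >= s[i]: TP = positives at or above i.
    pos_below = np.concatenate([[0], np.cumsum(y)])  # positives strictly before index i
    uniq_idx = np.flatnonzero(np.diff(s, prepend=np.nan))
    best_tss, best_thr = -np.inf, s[0]
    for i in uniq_idx:
        tp = n1 - pos_below[i]
        fp = (y.size - i) - tp
        sens = tp / n1
        spec = (n0 - fp) / n0
        tss = sens + spec - 1.0
        if tss > best_tss + 1e-12:
            best_tss, best_thr = tss, s[i]
    return float(best_thr)


def compute_metrics(
    scores: np.ndarray,
    labels: np.ndarray,
    threshold: float | None = None,
) -> EvalReport:
    """AUC (Mann–Whitney form) and threshold metrics (kappa, TSS).

    When ``threshold`` is None the max-TSS threshold is used, the common
    choice for presence/absence SDM evaluation.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    auc = auc_mann_whitney(scores, labels)
    if threshold is None:
        threshold = max_tss_threshold(scores, labels)
    pred = scores >= threshold
    tp = float(np.sum(pred & (labels == 1)))
    fn = float(np.sum(~pred & (labels == 1)))
    tn = float(np.sum(~pred & (labels == 0)))
    fp = float(np.sum(pred & (labels == 0)))
    m = metrics_from_confusion(tp, fn, tn, fp)
    return EvalReport(
        auc=auc,
        kappa=m["kappa"],
        tss=m["tss"],
        threshold=float(threshold),
        sensitivity=m["sensitivity"],
        specificity=m["specificity"],
    )


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _predictor_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in ("cell_id", "label")]


def fit_and_cross_validate(
    table: pd.DataFrame,
    k_folds: int = 10,
    train_frac: float = 0.7,
    n_repeats: int = 1,
    seed: int = 0,
    n_estimators: int = 300,
) -> tuple[RandomForestClassifier, EvalReport]:
    """Stratified k-fold cross-validation of a random-forest classifier.

    Within each fold, ``train_frac`` of the non-held-out rows (stratified)
    train the model; the held-out fold is scored. Reported AUC/kappa/TSS are
    fold means; the returned model is refit on the full table.
    """
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    cols = _predictor_columns(table)
    X = table[cols]
    y = table["label"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("training table must contain both classes")

    fold_rows = []
    for rep in range(n_repeats):
        skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed + 1000 * rep)
        for fold, (pool_idx, test_idx) in enumerate(skf.split(X, y)):
            if 0 < train_frac < 1:
                train_idx, _ = train_test_split(
                    pool_idx,
                    train_size=train_frac,
                    stratify=y[pool_idx],
                    random_state=seed + 1000 * rep + fold,
                )
            else:
                train_idx = pool_idx
            rf = RandomForestClassifier(
                n_estimators=n_estimators,
                random_state=seed + 1000 * rep + fold,
                n_jobs=1,
            )
            rf.fit(X.iloc[train_idx], y[train_idx])
            scores = rf.predict_proba(X.iloc[test_idx])[:, 1]
            m = compute_metrics(scores, y[test_idx])
            fold_rows.append(
                {"repeat": rep, "fold": fold, "auc": m.auc, "kappa": m.kappa,
                 "tss": m.tss, "threshold": m.threshold}
            )
    per_fold = pd.DataFrame(fold_rows)
    model = RandomForestClassifier(n_estimators=n_estimators, random_state=seed, n_jobs=1)
    model.fit(X, y)
    report = EvalReport(
        auc=float(per_fold["auc"].mean()),
        kappa=float(per_fold["kappa"].mean()),
        tss=float(per_fold["tss"].mean()),
        threshold=float(per_fold["threshold"].mean()),
        sensitivity=np.nan,
        specificity=np.nan,
        per_fold=per_fold,
    )
    return model, report


def permutation_importance(
    model,
    table: pd.DataFrame,
    n_perm: int = 10,
    seed: int = 0,
    eval_frac: float = 0.3,
) -> pd.Series:
    """Per-predictor contribution (%) from held-out permutation AUC drop.

    A clone of the model is refit on a stratified (1 - eval_frac) share of
    the table and scored on the held-out rest; each predictor is shuffled
    ``n_perm`` times there and its raw importance is the mean AUC drop
    (clipped at zero), normalized so contributions sum to 100. Held-out
    evaluation keeps overfit noise predictors from claiming importance;
    ``eval_frac=0`` falls back to in-sample evaluation on the given model.
    """
    from sklearn.base import clone

    cols = _predictor_columns(table)
    y_all = table["label"].to_numpy()
    if eval_frac > 0:
        fit_idx, eval_idx = train_test_split(
            np.arange(len(table)), test_size=eval_frac, stratify=y_all, random_state=seed
        )
        model = clone(model).fit(table.iloc[fit_idx][cols], y_all[fit_idx])
        X = table.iloc[eval_idx][cols].reset_index(drop=True)
        y = y_all[eval_idx]
    else:
        X = table[cols].copy()
        y = y_all
    base = auc_mann_whitney(model.predict_proba(X)[:, 1], y)
    rng = np.random.default_rng(seed)
    drops = {}
    for col in cols:
        original = X[col].to_numpy().copy()
        acc = 0.0
        for _ in range(n_perm):
            X[col] = rng.permutation(original)
            acc += base - auc_mann_whitney(model.predict_proba(X)[:, 1], y)
        X[col] = original
        drops[col] = max(0.0, acc / n_perm)
    s = pd.Series(drops)
    total = s.sum()
    if total <= 0:
        return s * 0.0
    return 100.0 * s / total


# ---------------------------------------------------------------------------
# Natural breaks (Fisher–Jenks)
# ---------------------------------------------------------------------------

def _fisher_jenks_weighted(values: np.ndarray, weights: np.ndarray, k: int) -> np.ndarray:
    """Exact optimal 1-D partition (weighted within-class SSD) by dynamic
    programming; values must be sorted ascending. Returns the index of the
    last element of each class."""
    n = values.size
    w = np.concatenate([[0.0], np.cumsum(weights)])
    s1 = np.concatenate([[0.0], np.cumsum(weights * values)])
    s2 = np.concatenate([[0.0], np.cumsum(weights * values**2)])

    def cost(i, j):
        # within-class SSD of values[i..j] inclusive; i, j arrays ok
        cw = w[j + 1] - w[i]
        c1 = s1[j + 1] - s1[i]
        c2 = s2[j + 1] - s2[i]
        return c2 - np.where(cw > 0, c1**2 / np.where(cw > 0, cw, 1.0), 0.0)

    idx = np.arange(n)
    dp = cost(np.zeros(n, dtype=int), idx)
    back = np.zeros((k, n), dtype=int)
    for m in range(1, k):
        new_dp = np.full(n, np.inf)
        for j in range(m, n):
            i = np.arange(m, j + 1)  # class m starts at i
            total = dp[i - 1] + cost(i, np.full(i.size, j))
            best = int(np.argmin(total))
            new_dp[j] = total[best]
            back[m, j] = m + best
        dp = new_dp
    ends = np.empty(k, dtype=int)
    j = n - 1
    for m in range(k - 1, -1, -1):
        ends[m] = j
        j = back[m, j] - 1
    return ends


def jenks_breaks(values: np.ndarray, n_classes: int) -> np.ndarray:
    """Natural-breaks class bounds minimizing within-class squared deviation.

    Exact Fisher dynamic program (not the common heuristic). Returns the
    upper bound of each class, ascending; the last bound is max(values).
    """
    v = np.sort(np.asarray(values, dtype=float).ravel())
    if v.size == 0:
        raise ValueError("empty input")
    uniq, counts = np.unique(v, return_counts=True)
    if n_classes < 1 or n_classes > uniq.size:
        raise ValueError(f"n_classes must be in [1, {uniq.size}] (distinct values)")
    ends = _fisher_jenks_weighted(uniq, counts.astype(float), n_classes)
    return uniq[ends]


def _binned_jenks(values: np.ndarray, n_classes: int, max_bins: int = 1024) -> np.ndarray:
    """Jenks on large arrays via exact weighted DP over value bins."""
    uniq, counts = np.unique(np.asarray(values, dtype=float).ravel(), return_counts=True)
    if uniq.size <= max_bins:
        k = min(n_classes, uniq.size)
        return uniq[_fisher_jenks_weighted(uniq, counts.astype(float), k)]
    edges = np.linspace(uniq[0], uniq[-1], max_bins + 1)
    mids = (edges[:-1] + edges[1:]) / 2.0
    hist, _ = np.histogram(values, bins=edges)
    keep = hist > 0
    ends = _fisher_jenks_weighted(mids[keep], hist[keep].astype(float), n_classes)
    return mids[keep][ends]


def classify_probability_surface(
    p: np.ndarray,
    mask: np.ndarray | None = None,
    occurrence_p: np.ndarray | None = None,
    epsilon: float = 0.05,
    calibration_quantiles: tuple[float, float, float] = (0.05, 0.25, 0.5),
) -> np.ndarray:
    """Four-level suitability classes from a probability surface.

    Natural breaks with k = 4 on cells above ``epsilon`` give provisional
    class bounds; cells at or below epsilon are forced to level 0
    (unsuitable). If probabilities at occurrence cells are supplied, the
    three level boundaries may each be *lowered* to at most the
    corresponding occurrence-probability quantile (order preserved) — a
    monotone calibration encoding "denser records mean higher suitability".
    Returns uint8 levels 0..3 (255 outside the mask); levels are monotone
    in p.
    """
    p = np.asarray(p, dtype=float)
    if mask is None:
        mask = ~np.isnan(p)
    levels = np.full(p.shape, 0, dtype=np.uint8)
    vals = p[mask & (p > epsilon)]
    if vals.size:
        uniq = np.unique(vals)
        k_eff = min(4, uniq.size)
        bounds = _binned_jenks(vals, k_eff)  # upper bound per class
        cuts = bounds[:-1]  # boundaries between the k_eff classes
        if occurrence_p is not None and cuts.size == 3:
            occ = np.asarray(occurrence_p, dtype=float)
            occ = occ[~np.isnan(occ)]
            if occ.size:
                qs = np.quantile(occ, calibration_quantiles)
                cuts = np.minimum(cuts, qs)
                cuts = np.maximum.accumulate(cuts)  # keep boundaries ordered
        inside = mask & (p > epsilon)
        # class c: p <= cuts[c] (first match), else top class; shift so the
        # top class is always level 3 when fewer than 4 classes exist.
        cls = np.searchsorted(cuts, p[inside], side="left")
        levels[inside] = (cls + (4 - k_eff)).astype(np.uint8)
    levels[~mask] = 255
    return levels


def predict_probability_surface(model, grid: ClimateGrid) -> np.ndarray:
    """Model probabilities over the grid's land cells; NaN elsewhere."""
    mask = grid.geometry.land_mask
    bio = bioclim_variables(grid).reshape(-1, 19)[mask.ravel()]
    frame = pd.DataFrame(bio, columns=list(BIOCLIM_NAMES))
    cols = list(getattr(model, "feature_names_in_", BIOCLIM_NAMES))
    scores = model.predict_proba(frame[cols])[:, 1]
    out = np.full(mask.shape, np.nan)
    out[mask] = scores
    return out
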