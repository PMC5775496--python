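"""Locus quality-control filters, imputation, and redundancy pruning.

The filter chain mirrors standard SNP-panel preparation: drop loci with
pooled minor-allele frequency below 5% ("below" read literally: MAF exactly
at the threshold is retained), drop loci with more than 5% missing calls,
impute the sparse remainder with a forest-proximity imputer, then prune to
"top loci" — a greedy scan in descending global-FST order that keeps a
locus only if its FST clears a floor and its genotype correlation (R²,
a composite linkage-disequilibrium proxy) with every already-kept locus
stays at or below a ceiling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .forest import ForestConfig, grow_forest
from .matrix import GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass
class FilterConfig:
    maf_min: float = 0.05
    missing_max: float = 0.05
    r2_max: float = 0.2
    fst_min: float = 0.05
    impute_trees: int = 5000
    impute_iters: int = 5
    seed: int = 0

    def __post_init__(self):
        for name in ("maf_min", "missing_max", "r2_max", "fst_min"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.impute_trees < 1 or self.impute_iters < 1:
            raise ValueError("impute_trees and impute_iters must be positive")


def filter_maf(m: GenotypeMatrix, maf_min: float = 0.05):
    """Keep loci with pooled MAF >= maf_min (non-missing calls only).

    Returns ``(filtered matrix, removed locus ids)``.  Loci with no calls at
    all have undefined MAF and are removed.
    """
    minor, total = m.minor_allele_counts()
    with np.errstate(invalid="ignore"):
        f = np.where(total > 0, minor / np.maximum(total, 1), np.nan)
    maf = np.minimum(f, 1.0 - f)
    keep = maf >= maf_min
    removed = [str(l) for l in m.locus_ids[~keep]]
    if not keep.any():
        log.warning("MAF filter removed every locus")
    return m.subset_loci(list(m.locus_ids[keep])), removed


def filter_missing(m: GenotypeMatrix, missing_max: float = 0.05):
    """Keep loci whose missing rate across all individuals is <= missing_max."""
    rate = np.isnan(m.dosages).mean(axis=0)
    keep = rate <= missing_max
    removed = [str(l) for l in m.locus_ids[~keep]]
    if not keep.any():
        log.warning("missingness filter removed every locus")
    return m.subset_loci(list(m.locus_ids[keep])), removed


def _snap(v: np.ndarray) -> np.ndarray:
    """Snap continuous values to the nearest dosage code."""
    return np.where(v < 0.25, 0.0, np.where(v < 0.75, 0.5, 1.0))


def _pop_mode_fill(m: GenotypeMatrix) -> np.ndarray:
    """Initialize missing cells to the within-population per-locus mode
    (global mode where a population has no calls at a locus)."""
    X = m.dosages.copy()
    codes = np.array([0.0, 0.5, 1.0])

    def mode(col):  # most frequent code, ties -> lowest dosage
        obs = col[~np.isnan(col)]
        if not obs.size:
            return np.nan
        counts = [(obs == c).sum() for c in codes]
        return codes[int(np.argmax(counts))]

    global_modes = np.array([mode(X[:, j]) for j in range(m.n_loci)])
    if np.isnan(global_modes).any():
        bad = m.locus_ids[np.isnan(global_modes)][0]
        raise ValueError(f"locus {bad!r} is 100% missing; cannot impute")
    for pop in m.population_names:
        rows = np.flatnonzero(m.populations == pop)
        block = X[rows]
        miss = np.isnan(block)
        if not miss.any():
            continue
        for j in np.flatnonzero(miss.any(axis=0)):
            v = mode(block[:, j])
            block[miss[:, j], j] = global_modes[j] if np.isnan(v) else v
        X[rows] = block
    return X


def _forest_proximity(X: np.ndarray, labels, ntree: int, seed: int) -> np.ndarray:
    """Co-leaf proximity matrix from a forest predicting population labels."""
    n = X.shape[0]
    forest = grow_forest(X, labels, ForestConfig(ntree=ntree, seed=seed))
    prox = np.zeros((n, n))
    for t in forest.trees:
        leaf_id = np.zeros(n, dtype=np.int32)
        node = np.zeros(n, dtype=np.int32)
        active = np.arange(n)
        while active.size:
            nd = node[active]
            at_leaf = t.leaf[nd] >= 0
            leaf_id[active[at_leaf]] = nd[at_leaf]
            active = active[~at_leaf]
            if not active.size:
                break
            nd = node[active]
            go_left = X[active, t.feature[nd]] < t.thr[nd]
            node[active] = np.where(go_left, t.left[nd], t.right[nd])
        for leaf in np.unique(leaf_id):
            g = np.flatnonzero(leaf_id == leaf)
            prox[np.ix_(g, g)] += 1.0
    return prox / len(forest.trees)


def impute_missing(m: GenotypeMatrix, cfg: FilterConfig | None = None) -> GenotypeMatrix:
    """Fill missing dosages with a forest-proximity imputer.

    Missing cells start at the within-population per-locus mode; each of
    ``cfg.impute_iters`` rounds grows a forest of ``cfg.impute_trees`` trees
    predicting the population label, and replaces every originally-missing
    cell with the proximity-weighted average of the observed dosages at that
    locus, snapped to the nearest code.  Observed cells are never altered.
    """
    cfg = cfg or FilterConfig()
    miss = np.isnan(m.dosages)
    if not miss.any():
        return m.copy()
    X = _pop_mode_fill(m)
    obs = ~miss
    for it in range(cfg.impute_iters):
        prox = _forest_proximity(X, m.populations, cfg.impute_trees, cfg.seed + it)
        np.fill_diagonal(prox, 0.0)
        for j in np.flatnonzero(miss.any(axis=0)):
            rows_obs = np.flatnonzero(obs[:, j])
            vals = m.dosages[rows_obs, j]
            for i in np.flatnonzero(miss[:, j]):
                w = prox[i, rows_obs]
                tot = w.sum()
                if tot > 0:
                    X[i, j] = float(_snap(np.array([w @ vals / tot]))[0])
    out = m.copy()
    out.dosages = X
    return out


def _pairwise_r2(x: np.ndarray, Y: np.ndarray, min_complete: int = 10):
    """Squared Pearson correlation of x with each column of Y over
    pairwise-complete rows; pairs with < min_complete complete rows get 0."""
    vx = ~np.isnan(x)
    vY = ~np.isnan(Y)
    valid = vx[:, None] & vY
    npair = valid.sum(axis=0)
    xs = np.where(valid, x[:, None], 0.0)
    ys = np.where(valid, Y, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        n = np.maximum(npair, 1)
        mx = xs.sum(axis=0) / n
        my = ys.sum(axis=0) / n
        cov = (xs * ys).sum(axis=0) / n - mx * my
        vxv = (xs**2).sum(axis=0) / n - mx**2
        vyv = (ys**2).sum(axis=0) / n - my**2
        r2 = cov**2 / (vxv * vyv)
    r2 = np.where((vxv <= 0) | (vyv <= 0), np.where(npair >= min_complete, 0.0, 0.0), r2)
    few = npair < min_complete
    if few.any():
        log.debug("%d locus pairs with <%d complete individuals treated as R²=0",
                  int(few.sum()), min_complete)
    r2[few] = 0.0
    return np.nan_to_num(r2, nan=0.0)


def prune_top_loci(m: GenotypeMatrix, stats: pd.DataFrame, r2_max: float = 0.2,
                   fst_min: float = 0.05) -> list[str]:
    """Greedy "top loci" pruning.

    Scan loci in descending global-FST order (ties by locus id) and keep a
    locus iff its global θ >= fst_min and its dosage R² with every
    already-kept locus is <= r2_max.  Returns kept ids in scan order, which
    is independent of the input column order.
    """
    missing_stats = [str(l) for l in m.locus_ids if l not in stats.index]
    if missing_stats:
        raise ValueError(f"no stats for loci: {missing_stats[:5]}")
    theta = stats["global_theta"]
    order = sorted(
        (str(l) for l in m.locus_ids),
        key=lambda l: (-(theta[l] if np.isfinite(theta[l]) else -np.inf), l),
    )
    kept: list[str] = []
    kept_cols: list[np.ndarray] = []
    col = {str(l): m.dosages[:, j] for j, l in enumerate(m.locus_ids)}
    for l in order:
        t = theta[l]
        if not np.isfinite(t) or t < fst_min:
            continue
        if kept_cols:
            r2 = _pairwise_r2(col[l], np.column_stack(kept_cols))
            if (r2 > r2_max).any():
                continue
        kept.append(l)
        kept_cols.append(col[l])
    return kept


def apply_filters(m: GenotypeMatrix, cfg: FilterConfig | None = None):
    """Full QC chain: MAF -> missingness -> imputation -> top-loci pruning.

    Returns ``(filtered matrix, report)`` where the report is a DataFrame of
    (locus, reason, value) for every removed locus.
    """
    from . import fst as fst_mod

    cfg = cfg or FilterConfig()
    report = []
    m1, rm_maf = filter_maf(m, cfg.maf_min)
    report += [(l, "maf", cfg.maf_min) for l in rm_maf]
    m2, rm_miss = filter_missing(m1, cfg.missing_max)
    report += [(l, "missing", cfg.missing_max) for l in rm_miss]
    m3 = impute_missing(m2, cfg)
    stats = fst_mod.locus_stats(m3)
    kept = prune_top_loci(m3, stats, cfg.r2_max, cfg.fst_min)
    dropped = set(map(str, m3.locus_ids)) - set(kept)
    report += [(l, "top_loci", float(stats.loc[l, "global_theta"])) for l in sorted(dropped)]
    out = m3.subset_loci(kept)
    return out, pd.DataFrame(report, columns=["locus", "reason", "value"])
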