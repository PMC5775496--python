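"""Weir–Cockerham F-statistics and per-locus summaries.

Implements the Weir & Cockerham (1984) variance-components estimator θ of
F_ST for diploid bi-allelic data: per locus, the among-population (a),
among-individual-within-population (b) and within-individual (c) components
are computed from per-population complete-case sample sizes, allele
frequencies and observed heterozygote proportions, and

    θ = a / (a + b + c).

Multi-locus values are ratios of summed components (ratio of sums, not mean
of ratios).  Negative estimates are reported as computed — clamping is
applied nowhere.  Monomorphic loci (a + b + c = 0) are undefined (NaN) and
rank last.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .matrix import GenotypeMatrix

log = logging.getLogger(__name__)


def wc_components(m: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus WC84 variance components (a, b, c).

    Missing genotypes are handled by per-locus complete-case sample sizes;
    populations with no called individuals at a locus drop out of that
    locus's estimate.  Loci where fewer than two populations have data, or
    where the average sample size is 1, are NaN in all three components.
    """
    pops = m.population_names
    if len(pops) < 2:
        raise ValueError("Weir-Cockerham theta needs at least 2 populations")
    p_loci = m.n_loci
    called = ~np.isnan(m.dosages)
    r_max = len(pops)

    n = np.zeros((r_max, p_loci))       # called individuals per pop x locus
    p_freq = np.zeros((r_max, p_loci))  # minor-allele frequency
    het = np.zeros((r_max, p_loci))     # observed heterozygote proportion
    for i, pop in enumerate(pops):
        rows = m.populations == pop
        c_pop = called[rows]
        d_pop = m.dosages[rows]
        n[i] = c_pop.sum(axis=0)
        with np.errstate(invalid="ignore"):
            p_freq[i] = np.where(c_pop, 1.0 - d_pop, 0.0).sum(axis=0) / np.maximum(n[i], 1)
            het[i] = np.where(c_pop, d_pop == 0.5, 0.0).sum(axis=0) / np.maximum(n[i], 1)

    present = n > 0
    r = present.sum(axis=0).astype(float)          # pops with data, per locus
    n_tot = n.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        nbar = n_tot / r
        nc = (n_tot - (n**2).sum(axis=0) / n_tot) / (r - 1.0)
        pbar = (n * p_freq).sum(axis=0) / n_tot
        s2 = (n * (p_freq - pbar) ** 2).sum(axis=0) / ((r - 1.0) * nbar)
        hbar = (n * het).sum(axis=0) / n_tot

        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0

    bad = (r < 2) | (nbar <= 1) | ~np.isfinite(nc) | (nc <= 0)
    for comp in (a, b, c):
        comp[bad] = np.nan
    return a, b, c


def wc_theta_locus(m: GenotypeMatrix) -> np.ndarray:
    """Per-locus WC84 θ across all populations; NaN where undefined
    (monomorphic locus or insufficient data)."""
    a, b, c = wc_components(m)
    denom = a + b + c
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.where(denom != 0, a / denom, np.nan)
    return theta


def wc_theta_multilocus(a, b, c) -> float:
    """Multi-locus θ as the ratio of summed components over defined loci."""
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    ok = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    if not ok.any():
        return np.nan
    denom = (a[ok] + b[ok] + c[ok]).sum()
    if denom == 0:
        return np.nan
    return float(a[ok].sum() / denom)


def multilocus_theta(m: GenotypeMatrix) -> float:
    """Convenience: multi-locus WC84 θ of a matrix."""
    return wc_theta_multilocus(*wc_components(m))


def pairwise_fst(m: GenotypeMatrix) -> pd.DataFrame:
    """Multi-locus θ for every pair of populations, as a symmetric labelled
    matrix with zeros on the diagonal.  Populations with fewer than two
    individuals are excluded with a warning."""
    pops = m.population_names
    sizes = {p: int((m.populations == p).sum()) for p in pops}
    keep = [p for p in pops if sizes[p] >= 2]
    for p in pops:
        if sizes[p] < 2:
            log.warning("population %r has %d individual(s); excluded from "
                        "pairwise FST", p, sizes[p])
    if len(keep) < 2:
        raise ValueError("pairwise FST needs at least 2 populations of size >= 2")
    out = pd.DataFrame(0.0, index=keep, columns=keep)
    for i, p1 in enumerate(keep):
        for p2 in keep[i + 1:]:
            sub = m.subset_individuals(np.isin(m.populations, [p1, p2]))
            t = multilocus_theta(sub)
            out.loc[p1, p2] = out.loc[p2, p1] = t
    return out


def locus_stats(m: GenotypeMatrix) -> pd.DataFrame:
    """Per-locus summary: MAF, missing rate and global WC84 θ.

    MAF is the pooled frequency of the rarer allele (≤ 0.5 by definition,
    whatever the dosage orientation of the input).
    """
    minor, total = m.minor_allele_counts()
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(total > 0, minor / np.maximum(total, 1), np.nan)
    maf = np.minimum(f, 1.0 - f)
    missing = np.isnan(m.dosages).mean(axis=0)
    theta = wc_theta_locus(m) if len(m.population_names) >= 2 else np.full(m.n_loci, np.nan)
    return pd.DataFrame(
        {
            "locus_id": list(m.locus_ids),
            "maf": maf,
            "missing_rate": missing,
            "global_theta": theta,
        }
    ).set_index("locus_id")


def rank_by_global_fst(stats: pd.DataFrame) -> list[str]:
    """Locus ids in descending global θ; ties break by locus id; undefined
    (NaN) θ ranks last."""
    theta = stats["global_theta"].to_numpy(dtype=float)
    key = np.where(np.isnan(theta), -np.inf, theta)
    order = sorted(range(len(stats)), key=lambda j: (-key[j], str(stats.index[j])))
    return [str(stats.index[j]) for j in order]
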