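"""Genetic stock identification by leave-one-out self-assignment.

The baseline is built from *all* individuals (training and holdout): per
population and panel locus, the minor-allele count and the total number of
called alleles.  An individual's assignment likelihood removes its own two
alleles from its population's counts first (leave-one-out), then scores each
population with Hardy–Weinberg genotype probabilities at Dirichlet(½, ½)-
smoothed allele frequencies

    q = (count + ½) / (total + 1),
    P(genotype) = q², 2q(1-q) or (1-q)²,

accumulated in log space across panel loci (missing calls skipped), with a
uniform prior over populations.  Headline accuracy uses holdout individuals
only — the training/holdout split plus leave-one-out is what keeps the
self-assignment estimate honest at these sample sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import GenotypeMatrix
from .panels import Panel, SplitSpec

_LOG2 = np.log(2.0)


@dataclass
class Baseline:
    """Per population x panel-locus allele counts."""

    populations: list[str]
    locus_ids: list[str]
    minor_counts: np.ndarray  # (K, p) minor-allele counts
    totals: np.ndarray        # (K, p) called alleles (2 x called individuals)

    def __post_init__(self):
        self.minor_counts = np.asarray(self.minor_counts, dtype=float)
        self.totals = np.asarray(self.totals, dtype=float)
        if (self.minor_counts < 0).any() or (self.minor_counts > self.totals).any():
            raise ValueError("counts must satisfy 0 <= count <= total")

    def frequencies(self, smoothed: bool = True) -> np.ndarray:
        if smoothed:
            return (self.minor_counts + 0.5) / (self.totals + 1.0)
        with np.errstate(invalid="ignore"):
            return np.where(self.totals > 0,
                            self.minor_counts / np.maximum(self.totals, 1), 0.5)


def build_baseline(m: GenotypeMatrix, panel: Panel | list) -> Baseline:
    """Count minor alleles per population over non-missing calls of all
    individuals, restricted to the panel loci."""
    loci = panel.loci if isinstance(panel, Panel) else list(panel)
    sub = m.subset_loci(loci)
    pops = m.population_names
    K, p = len(pops), len(loci)
    minor = np.zeros((K, p))
    total = np.zeros((K, p))
    for k, pop in enumerate(pops):
        d = sub.dosages[sub.populations == pop]
        called = ~np.isnan(d)
        minor[k] = np.where(called, 2.0 * (1.0 - d), 0.0).sum(axis=0)
        total[k] = 2.0 * called.sum(axis=0)
    if p > 0:
        empty = (total.sum(axis=1) == 0)
        if empty.any():
            bad = [pops[k] for k in np.flatnonzero(empty)]
            raise ValueError(f"population(s) {bad} have no called alleles at any "
                             "panel locus")
    return Baseline(pops, loci, minor, total)


def _loglik_all(d_row, called, minor_counts, totals):
    """Log-likelihood of one individual's called dosages under each row of
    (minor_counts, totals) -> vector over populations."""
    m_all = 2.0 * (1.0 - d_row[called])
    q = (minor_counts[:, called] + 0.5) / (totals[:, called] + 1.0)
    het = d_row[called] == 0.5
    return (m_all * np.log(q) + (2.0 - m_all) * np.log1p(-q)).sum(axis=1) \
        + het.sum() * _LOG2


def loo_posterior(individual_id: str, m: GenotypeMatrix, baseline: Baseline,
                  leave_out: bool = True) -> np.ndarray:
    """Posterior over populations for one individual (uniform prior).

    With ``leave_out``, the individual's own alleles are first subtracted
    from its population's baseline counts (it must then be in the matrix's
    population set).  Loci with missing calls are skipped; with no called
    panel loci the posterior is uniform.
    """
    i = int(np.flatnonzero(m.individual_ids == individual_id)[0])
    sub = m.subset_loci(baseline.locus_ids)
    d = sub.dosages[i]
    called = ~np.isnan(d)
    K = len(baseline.populations)
    if called.sum() == 0:
        return np.full(K, 1.0 / K)
    minor = baseline.minor_counts.copy()
    total = baseline.totals.copy()
    if leave_out:
        pop = str(m.populations[i])
        k = baseline.populations.index(pop)
        m_i = np.where(called, 2.0 * (1.0 - d), 0.0)
        minor[k] -= m_i
        total[k] -= np.where(called, 2.0, 0.0)
        if (minor[k] < -1e-9).any() or (total[k] < -1e-9).any():
            raise RuntimeError("leave-one-out produced negative counts: the "
                               "baseline was not built from this matrix")
    ll = _loglik_all(d, called, minor, total)
    ll -= ll.max()
    w = np.exp(ll)
    return w / w.sum()


def self_assign(m: GenotypeMatrix, panel: Panel | list,
                split: SplitSpec | None = None) -> pd.DataFrame:
    """Leave-one-out assignment of every individual against the all-
    individuals baseline.

    Returns one row per individual: true and assigned population, holdout
    flag, and the posterior for each population.  Argmax ties resolve to the
    lowest population label.
    """
    baseline = build_baseline(m, panel)
    K = len(baseline.populations)
    sub = m.subset_loci(baseline.locus_ids)
    holdout = split.is_holdout(m.individual_ids) if split is not None \
        else np.ones(m.n_individuals, dtype=bool)
    pop_index = {p: k for k, p in enumerate(baseline.populations)}

    rows = []
    post_mat = np.empty((m.n_individuals, K))
    for i, ind in enumerate(m.individual_ids):
        d = sub.dosages[i]
        called = ~np.isnan(d)
        if called.sum() == 0:
            post = np.full(K, 1.0 / K)
        else:
            minor = baseline.minor_counts.copy()
            total = baseline.totals.copy()
            k = pop_index[str(m.populations[i])]
            m_i = np.where(called, 2.0 * (1.0 - d), 0.0)
            minor[k] -= m_i
            total[k] -= np.where(called, 2.0, 0.0)
            ll = _loglik_all(d, called, minor, total)
            ll -= ll.max()
            w = np.exp(ll)
            post = w / w.sum()
        post_mat[i] = post
        rows.append(
            {
                "individual": str(ind),
                "true_pop": str(m.populations[i]),
                "assigned_pop": baseline.populations[int(post.argmax())],
                "holdout": bool(holdout[i]),
            }
        )
    out = pd.DataFrame(rows)
    for k, pop in enumerate(baseline.populations):
        out[f"post_{pop}"] = post_mat[:, k]
    return out


def accuracy_summary(results: pd.DataFrame, holdout_only: bool = True):
    """Overall and per-population percent-correct.

    Returns ``(overall_pct, per_population_pct)`` where the second is a
    Series indexed by true population.
    """
    r = results[results["holdout"]] if holdout_only else results
    if not len(r):
        raise ValueError("no holdout individuals to score")
    correct = r["true_pop"] == r["assigned_pop"]
    overall = 100.0 * correct.mean()
    per_pop = 100.0 * correct.groupby(r["true_pop"]).mean()
    return float(overall), per_pop


def simulate_baseline_genotypes(baseline: Baseline, n_per_pop: int, seed: int = 0,
                                smoothed: bool = True) -> GenotypeMatrix:
    """Bootstrap-style genotypes drawn from baseline allele frequencies.

    Per population, ``n_per_pop`` individuals are drawn locus-independently
    under Hardy–Weinberg at the (by default Dirichlet-smoothed) baseline
    frequencies.  Meant for power checks, not for headline accuracy.
    """
    if not baseline.locus_ids:
        raise ValueError("cannot simulate from an empty baseline")
    rng = np.random.default_rng(seed)
    q = baseline.frequencies(smoothed=smoothed)
    ids, pops, rows = [], [], []
    for k, pop in enumerate(baseline.populations):
        counts = rng.binomial(2, q[k], size=(n_per_pop, len(baseline.locus_ids)))
        rows.append(1.0 - counts / 2.0)
        ids.extend(f"{pop}_sim{j + 1}" for j in range(n_per_pop))
        pops.extend([pop] * n_per_pop)
    return GenotypeMatrix(ids, pops, baseline.locus_ids, np.vstack(rows))
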