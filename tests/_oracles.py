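"""Independent reference implementations used only to cross-check the
package.  Everything here is deliberately scalar/naive and shares no code
with panelforge."""

from __future__ import annotations

import math

import numpy as np


def wc_theta_oracle(dosages, populations):
    """Per-locus Weir–Cockerham θ by the direct textbook formula, one locus
    and one population at a time.  dosages: (n, p) with NaN missing; minor
    allele frequency of an individual = 1 - dosage."""
    populations = np.asarray(populations)
    pops = sorted(set(populations))
    n_loci = dosages.shape[1]
    out = np.empty(n_loci)
    for j in range(n_loci):
        ns, ps, hs = [], [], []
        for pop in pops:
            col = dosages[populations == pop, j]
            col = col[~np.isnan(col)]
            if len(col) == 0:
                continue
            ns.append(len(col))
            ps.append(float(np.mean(1.0 - col)))
            hs.append(float(np.mean(col == 0.5)))
        r = len(ns)
        if r < 2:
            out[j] = math.nan
            continue
        nbar = sum(ns) / r
        if nbar <= 1:
            out[j] = math.nan
            continue
        nc = (sum(ns) - sum(n * n for n in ns) / sum(ns)) / (r - 1)
        if nc <= 0:
            out[j] = math.nan
            continue
        pbar = sum(n * p for n, p in zip(ns, ps)) / sum(ns)
        s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
        hbar = sum(n * h for n, h in zip(ns, hs)) / sum(ns)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        denom = a + b + c
        out[j] = a / denom if denom != 0 else math.nan
    return out


def greedy_prune_oracle(dosages, locus_ids, theta, r2_max, fst_min):
    """Exhaustive re-run of the greedy top-loci rule with plain numpy
    pairwise-complete correlations."""
    order = sorted(
        range(len(locus_ids)),
        key=lambda j: (
            -(theta[j] if np.isfinite(theta[j]) else -np.inf),
            str(locus_ids[j]),
        ),
    )
    kept = []
    for j in order:
        if not np.isfinite(theta[j]) or theta[j] < fst_min:
            continue
        ok = True
        for k in kept:
            x, y = dosages[:, j], dosages[:, k]
            good = ~np.isnan(x) & ~np.isnan(y)
            if good.sum() < 10:
                continue  # treated as r2 = 0
            xs, ys = x[good], y[good]
            if np.std(xs) == 0 or np.std(ys) == 0:
                continue
            r = np.corrcoef(xs, ys)[0, 1]
            if r * r > r2_max:
                ok = False
                break
        if ok:
            kept.append(j)
    return [str(locus_ids[j]) for j in kept]


def loo_posterior_oracle(dosage_row, own_pop, minor_counts, totals, pops,
                         leave_out=True):
    """Scalar leave-one-out assignment posterior.

    minor_counts/totals: dict pop -> list per locus.  Returns posterior in
    the order of ``pops`` (sorted labels, uniform prior)."""
    logliks = []
    for pop in pops:
        ll = 0.0
        for j, d in enumerate(dosage_row):
            if d is None or (isinstance(d, float) and math.isnan(d)):
                continue
            cnt = minor_counts[pop][j]
            tot = totals[pop][j]
            if leave_out and pop == own_pop:
                cnt -= 2 * (1 - d)
                tot -= 2
            q = (cnt + 0.5) / (tot + 1.0)
            if d == 0:
                ll += 2 * math.log(q)
            elif d == 0.5:
                ll += math.log(2) + math.log(q) + math.log(1 - q)
            else:
                ll += 2 * math.log(1 - q)
        logliks.append(ll)
    mx = max(logliks)
    w = [math.exp(l - mx) for l in logliks]
    s = sum(w)
    return [x / s for x in w]


def consensus_oracle(lists, k):
    """Brute-force set intersection of the top-k of each list."""
    common = set(lists[0][:k])
    for lst in lists[1:]:
        common &= set(lst[:k])
    return common
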