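"""Synthetic population-genotype generator.

Genotypes are simulated under the Balding–Nichols model: each locus has an
ancestral minor-allele frequency p drawn from a configurable distribution,
and each population's frequency is a Beta(p(1-F)/F, (1-p)(1-F)/F) draw whose
variance across populations is p(1-p)F — i.e. the model is parameterized
directly by the per-locus F_ST.  Individuals are Hardy–Weinberg draws from
their population's frequency; an optional two-level hierarchy composes a
between-region and a within-region Beta draw.

The default configuration emulates a low-differentiation salmonid SNP data
set: 5 populations of 30, thousands of loci whose per-locus global F_ST
mixture has mean 0.059 with a right tail topping out near 0.6 (85% of loci
at F = 0.0429, 15% at 0.15 — calibrated so the realized per-locus θ
distribution matches that target shape), and sparse missingness (0.08% of
cells).

Dosage orientation follows the package convention (0 = minor homozygote,
1 = major homozygote); after simulation each locus is re-oriented so the
minor-coded allele is the globally rarer one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import GenotypeMatrix

#: Default per-locus F_ST mixture: (fraction of loci, F) pairs, mean 0.059.
DEFAULT_FST_MIX = ((0.85, 0.0429), (0.15, 0.15))


@dataclass
class SimConfig:
    """Conditions for one synthetic data set.

    ``fst_mix`` is a tuple of (fraction, F) pairs; fractions must sum to 1.
    ``n_per_pop`` may be a single int or one count per population.
    ``hierarchy``, if given, is (n_regions, F_between, F_within): populations
    are split evenly over regions and the two Beta draws compose.
    """

    n_pops: int = 5
    n_per_pop: int | tuple = 30
    n_loci: int = 2000
    fst_mix: tuple = DEFAULT_FST_MIX
    maf_range: tuple = (0.05, 0.5)
    hierarchy: tuple | None = None
    missing_rate: float = 0.0008
    seed: int = 0

    def __post_init__(self):
        fracs = [f for f, _ in self.fst_mix]
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("fst_mix fractions must sum to 1")
        if any(not (0 < F < 1) for _, F in self.fst_mix):
            raise ValueError("fst_mix F levels must lie in (0, 1)")
        if isinstance(self.n_per_pop, int):
            self.n_per_pop = (self.n_per_pop,) * self.n_pops
        else:
            self.n_per_pop = tuple(self.n_per_pop)
        if len(self.n_per_pop) != self.n_pops:
            raise ValueError("n_per_pop length must equal n_pops")
        if any(n < 2 for n in self.n_per_pop):
            raise ValueError("each population needs at least 2 individuals")

    @property
    def mean_fst(self) -> float:
        return sum(f * F for f, F in self.fst_mix)


def _balding_nichols(rng, p, F):
    """One Beta draw per element of p with matching F (0 -> exactly p)."""
    p = np.asarray(p, dtype=float)
    F = np.broadcast_to(np.asarray(F, dtype=float), p.shape)
    out = p.copy()
    drift = F > 0
    if drift.any():
        ratio = (1.0 - F[drift]) / F[drift]
        out[drift] = rng.beta(p[drift] * ratio, (1.0 - p[drift]) * ratio)
    return out


def simulate_frequencies(cfg: SimConfig, rng=None):
    """Draw per-population minor-allele frequencies.

    Returns ``(freqs, locus_fst)``: frequencies of shape (n_pops, n_loci) and
    the per-locus F assigned from the mixture.  Loci are assigned to mixture
    components deterministically by proportion (first ``round(frac*n_loci)``
    loci to the first component, and so on), then the per-population draws
    are random.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    p_anc = rng.uniform(*cfg.maf_range, size=cfg.n_loci)
    locus_fst = np.empty(cfg.n_loci)
    start = 0
    for k, (frac, F) in enumerate(cfg.fst_mix):
        stop = cfg.n_loci if k == len(cfg.fst_mix) - 1 else start + round(frac * cfg.n_loci)
        locus_fst[start:stop] = F
        start = stop

    if cfg.hierarchy is None:
        freqs = np.vstack(
            [_balding_nichols(rng, p_anc, locus_fst) for _ in range(cfg.n_pops)]
        )
    else:
        n_regions, f_between, f_within = cfg.hierarchy
        region_of = np.arange(cfg.n_pops) % n_regions
        scale_b = locus_fst * f_between / (f_between + f_within)
        scale_w = locus_fst * f_within / (f_between + f_within)
        region_freqs = [
            _balding_nichols(rng, p_anc, scale_b) for _ in range(n_regions)
        ]
        freqs = np.vstack(
            [_balding_nichols(rng, region_freqs[region_of[i]], scale_w)
             for i in range(cfg.n_pops)]
        )
    return np.clip(freqs, 0.0, 1.0), locus_fst


def simulate_genotypes(freqs: np.ndarray, cfg: SimConfig, rng=None,
                       reorient: bool = True) -> GenotypeMatrix:
    """Draw a genotype matrix from per-population frequencies.

    Per individual and locus the minor-allele count is Binomial(2, q) and the
    dosage is ``1 - count/2`` (0 = minor homozygote).  Cells are masked
    missing independently at ``cfg.missing_rate``.  With ``reorient`` (the
    default) loci are re-labelled so the minor-coded allele is globally the
    rarer one (ties left alone); disable it to keep the raw orientation of
    ``freqs``.
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    n_pops, n_loci = freqs.shape
    rows, ids, pops = [], [], []
    for i in range(n_pops):
        n = cfg.n_per_pop[i]
        counts = rng.binomial(2, freqs[i], size=(n, n_loci))
        rows.append(1.0 - counts / 2.0)
        ids.extend(f"pop{i + 1}_{j + 1}" for j in range(n))
        pops.extend([f"pop{i + 1}"] * n)
    dosages = np.vstack(rows)
    if cfg.missing_rate > 0:
        mask = rng.random(dosages.shape) < cfg.missing_rate
        dosages[mask] = np.nan

    if reorient:  # minor allele = globally rarer allele
        called = ~np.isnan(dosages)
        with np.errstate(invalid="ignore"):
            minor_freq = np.nansum(1.0 - dosages, axis=0) / np.maximum(
                called.sum(axis=0), 1)
        flip = minor_freq > 0.5
        dosages[:, flip] = 1.0 - dosages[:, flip]
    return GenotypeMatrix(ids, pops, [f"L{j + 1}" for j in range(n_loci)], dosages)


def simulate(cfg: SimConfig):
    """Full draw: returns ``(matrix, truth)`` where truth records the
    per-locus simulated F and the per-population frequencies."""
    rng = np.random.default_rng(cfg.seed)
    freqs, locus_fst = simulate_frequencies(cfg, rng)
    m = simulate_genotypes(freqs, cfg, rng)
    truth = {"locus_fst": locus_fst, "freqs": freqs,
             "locus_ids": list(m.locus_ids)}
    return m, truth


# ---------------------------------------------------------------- fixtures
FIXTURE_NAMES = ("tiny_separable", "null_shuffled", "planted_signal", "duplicate_loci")


def make_fixture(name: str):
    """Small deterministic matrices with hand-verifiable expectations.

    Returns ``(matrix, manifest)``; the manifest is a dict of the properties
    a test can assert (expected θ values, panel members, accuracies).
    """
    rng = np.random.default_rng(12345)
    if name == "tiny_separable":
        # 3 pops x 10, 30 loci; each pop is the minor homozygote at its own
        # ten loci and major homozygote elsewhere -> fixed differences.
        n_pops, n_per, per_block = 3, 10, 10
        n_loci = n_pops * per_block
        dos = np.ones((n_pops * n_per, n_loci))
        for p in range(n_pops):
            dos[p * n_per:(p + 1) * n_per, p * per_block:(p + 1) * per_block] = 0.0
        m = GenotypeMatrix(
            [f"pop{p + 1}_{i + 1}" for p in range(n_pops) for i in range(n_per)],
            [f"pop{p + 1}" for p in range(n_pops) for _ in range(n_per)],
            [f"L{j + 1}" for j in range(n_loci)],
            dos,
        )
        manifest = {"expected_theta": 1.0, "expected_holdout_accuracy": 100.0}
    elif name == "null_shuffled":
        cfg = SimConfig(n_pops=4, n_per_pop=12, n_loci=60,
                        fst_mix=((1.0, 0.01),), missing_rate=0.0, seed=777)
        m, _ = simulate(cfg)
        labels = np.array(m.populations)
        rng.shuffle(labels)
        m = GenotypeMatrix(m.individual_ids, labels, m.locus_ids, m.dosages)
        manifest = {"n_pops": 4, "expected_accuracy_about": 25.0}
    elif name == "planted_signal":
        cfg = SimConfig(n_pops=3, n_per_pop=15, n_loci=100,
                        fst_mix=((0.10, 0.45), (0.90, 0.005)),
                        missing_rate=0.0, seed=99)
        m, truth = simulate(cfg)
        informative = [l for l, F in zip(truth["locus_ids"], truth["locus_fst"])
                       if F > 0.1]
        manifest = {"informative_loci": informative}
    elif name == "duplicate_loci":
        base, _ = simulate(SimConfig(n_pops=2, n_per_pop=10, n_loci=9,
                                     fst_mix=((1.0, 0.3),),
                                     missing_rate=0.0, seed=5))
        dos = np.column_stack([base.dosages, base.dosages[:, 0]])
        m = GenotypeMatrix(base.individual_ids, base.populations,
                           list(base.locus_ids) + ["L1_copy"], dos)
        manifest = {"duplicate_pair": ("L1", "L1_copy")}
    else:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    return m, manifest
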