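"""Building locus panels from a training subset of individuals.

Four selection routes produce ordered locus whitelists of matched sizes:

* **FST** — top-k loci by global Weir–Cockerham θ computed on the training
  individuals.
* **RF** — consensus of five independently seeded forest runs: loci ranked
  by MDA in every run, keeping those present in all five top-k lists.
* **RRF** — loci actually selected for splits by a regularized forest at
  penalty λ.
* **GRRF** — as RRF but with per-locus penalties guided by a single plain
  forest run's MDA, controlled by γ.

All selection sees only the training individuals of a stratified one-third
split; the holdout individuals exist solely for scoring assignment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import fst as fst_mod
from .forest import Forest, ForestConfig, RegularizationParams, grow_forest, \
    grow_regularized_forest, mda_importance
from .matrix import GenotypeMatrix

log = logging.getLogger(__name__)

METHODS = ("FST", "RF", "RRF", "GRRF")


@dataclass
class Panel:
    """An ordered locus whitelist tagged with how it was selected."""

    method: str
    parameter: float | int | None
    loci: list[str]

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("panel loci must be unique")

    @property
    def size(self) -> int:
        return len(self.loci)


@dataclass
class SplitSpec:
    """A stratified training/holdout split of individuals."""

    training_ids: list[str]
    holdout_ids: list[str]
    fraction: float
    seed: int

    def __post_init__(self):
        if set(self.training_ids) & set(self.holdout_ids):
            raise ValueError("training and holdout sets overlap")

    def is_holdout(self, individual_ids) -> np.ndarray:
        h = set(self.holdout_ids)
        return np.array([i in h for i in individual_ids])


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def training_split(m: GenotypeMatrix, fraction: float = 1 / 3,
                   seed: int = 0) -> SplitSpec:
    """Stratified random split: per population, round-half-up(n * fraction)
    individuals (at least 1) go to training, the rest to holdout."""
    rng = np.random.default_rng(seed)
    train, hold = [], []
    for pop in m.population_names:
        ids = sorted(m.individual_ids[m.populations == pop])
        if len(ids) < 2:
            raise ValueError(f"population {pop!r} has fewer than 2 individuals")
        k = max(1, _round_half_up(len(ids) * fraction))
        picked = rng.choice(len(ids), size=k, replace=False)
        chosen = {ids[i] for i in picked}
        train.extend(sorted(chosen))
        hold.extend(i for i in ids if i not in chosen)
    return SplitSpec(train, hold, fraction, seed)


def fst_rank_panel(stats, size: int) -> Panel:
    """Top ``size`` loci by global θ (training-individual stats)."""
    ranked = fst_mod.rank_by_global_fst(stats)
    if size > len(ranked):
        raise ValueError(f"requested {size} loci but only {len(ranked)} available")
    return Panel("FST", size, ranked[:size])


def ranked_importance_list(m_train: GenotypeMatrix, cfg: ForestConfig,
                           seed: int) -> list[str]:
    """One forest run's MDA ranking, truncated to positive-MDA loci.

    Order: descending MDA, ties by locus id.
    """
    run_cfg = ForestConfig(cfg.ntree, cfg.mtry, cfg.min_node, seed)
    f = grow_forest(m_train, cfg=run_cfg)
    mda = mda_importance(f, m_train, seed=seed)
    loci = list(m_train.locus_ids)
    order = sorted(range(len(loci)), key=lambda j: (-mda[j], str(loci[j])))
    return [str(loci[j]) for j in order if mda[j] > 0]


def rf_consensus_panel(importance_lists: list[list[str]], rank_level: int,
                       parameter=None) -> Panel:
    """Intersection of the top-k loci of all ranked lists.

    Panel order is by mean rank across lists; ties break by locus id.
    """
    for i, lst in enumerate(importance_lists):
        if rank_level > len(lst):
            raise ValueError(
                f"rank level {rank_level} exceeds length {len(lst)} of list {i + 1}"
            )
    tops = [set(lst[:rank_level]) for lst in importance_lists]
    common = set.intersection(*tops)
    mean_rank = {
        l: np.mean([lst.index(l) for lst in importance_lists]) for l in common
    }
    ordered = sorted(common, key=lambda l: (mean_rank[l], str(l)))
    return Panel("RF", parameter if parameter is not None else rank_level, ordered)


def consensus_sizes(importance_lists) -> np.ndarray:
    """size(k) of the consensus panel for every k up to the shortest list."""
    kmax = min(len(l) for l in importance_lists)
    pos = [{l: i for i, l in enumerate(lst)} for lst in importance_lists]
    entry_rank = []
    for l in importance_lists[0]:
        if all(l in p for p in pos):
            entry_rank.append(max(p[l] for p in pos) + 1)  # k at which l enters
    sizes = np.zeros(kmax + 1, dtype=int)
    for r in entry_rank:
        if r <= kmax:
            sizes[r] += 1
    return np.cumsum(sizes)  # sizes[k] = consensus size at rank level k


def sweep_panels(m_train: GenotypeMatrix, cfg: ForestConfig, method: str,
                 grid, n_runs: int = 5, size_tol: float = 0.10) -> list[Panel]:
    """One panel per grid value.

    * ``FST``: grid = panel sizes.
    * ``RF``: grid = *target* panel sizes; the rank level for each target is
      found from the consensus-size curve of ``n_runs`` seeded forest runs,
      warning when no level lands within ``size_tol`` of the target.
    * ``RRF``: grid = λ values.
    * ``GRRF``: grid = γ values, guided by a single fresh forest run's MDA.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("parameter grid is empty")
    if method == "FST":
        stats = fst_mod.locus_stats(m_train)
        return [fst_rank_panel(stats, int(g)) for g in grid]
    if method == "RF":
        lists = [ranked_importance_list(m_train, cfg, cfg.seed + r)
                 for r in range(n_runs)]
        sizes = consensus_sizes(lists)
        panels = []
        for target in grid:
            k = int(np.argmin(np.abs(sizes - int(target))))
            if k == 0 or abs(sizes[k] - target) > size_tol * target:
                log.warning("RF consensus: target size %d unreachable; closest "
                            "is %d at rank level %d", target, sizes[k], k)
            k = max(k, 1)
            panels.append(rf_consensus_panel(lists, k, parameter=k))
        return panels
    if method == "RRF":
        panels = []
        for lam in grid:
            _, sel = grow_regularized_forest(
                m_train, cfg=cfg, reg=RegularizationParams(lam=float(lam)))
            panels.append(Panel("RRF", float(lam), sel))
        return panels
    if method == "GRRF":
        guide_forest = grow_forest(m_train, cfg=cfg)
        base = mda_importance(guide_forest, m_train, seed=cfg.seed)
        panels = []
        for gamma in grid:
            _, sel = grow_regularized_forest(
                m_train, cfg=cfg,
                reg=RegularizationParams(lam=1.0, gamma=float(gamma),
                                         base_importance=base))
            panels.append(Panel("GRRF", float(gamma), sel))
        return panels
    raise ValueError(f"unknown method {method!r}")
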