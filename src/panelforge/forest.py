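"""Classification random forest with gain-penalty regularization.

Grown from scratch on dosage-coded genotypes, because the regularized and
guided-regularized variants need a per-feature penalty on Gini gain and a
selected-feature set shared across sequentially grown trees — machinery no
stock forest exposes.

Since dosages take only the ordered values {0, 0.5, 1}, every split is one
of two threshold tests (< 0.25 or < 0.75), which keeps node evaluation a
pair of small matrix products over the mtry sampled loci.

Regularization: a growing set F of selected loci starts empty; at each node
the candidate score of locus i is its Gini gain times a penalty λ_i if
i ∉ F, and the raw gain if i ∈ F.  The winning locus joins F.  With a
uniform penalty λ this is the regularized forest (RRF); the guided variant
(GRRF) sets λ_i = (1 - γ) λ + γ · imp_i where imp_i is a prior importance
(an MDA vector from a plain forest run) normalized to [0, 1].  Larger γ
shrinks penalties for unimportant loci and thus the selected panel.

Importance is the permutation mean decrease in accuracy (MDA): per tree, the
accuracy on that tree's out-of-bag cases minus the accuracy after permuting
one locus among those cases, averaged over trees (reported raw, unscaled).
A locus a tree never splits on contributes exactly zero for that tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import GenotypeMatrix

_GAIN_EPS = 1e-12
_THRESHOLDS = (0.25, 0.75)


@dataclass
class ForestConfig:
    """Forest hyperparameters.

    Defaults follow the study configuration for this data scale: error
    stabilizes by ~2000 trees, mtry at twice the square-root default beats
    the default and half-default, and a minimum node size of 5 lets large
    trees grow.
    """

    ntree: int = 2000
    mtry: int | None = None  # None -> 2 * ceil(sqrt(p)), capped at p
    min_node: int = 5
    seed: int = 0

    def resolve_mtry(self, p: int) -> int:
        m = self.mtry if self.mtry is not None else 2 * int(np.ceil(np.sqrt(p)))
        if not 1 <= m:
            raise ValueError("mtry must be >= 1")
        return min(m, p)


@dataclass
class RegularizationParams:
    """Penalty settings for RRF/GRRF.

    ``lam`` in (0, 1] is the uniform penalty (larger -> smaller penalty ->
    larger panel); ``gamma`` in [0, 1) mixes in a per-locus prior importance
    (larger -> smaller panel).  gamma > 0 requires ``base_importance``.
    """

    lam: float = 1.0
    gamma: float = 0.0
    base_importance: np.ndarray | None = None

    def penalties(self, p: int) -> np.ndarray:
        if not 0 < self.lam <= 1:
            raise ValueError("lambda must lie in (0, 1]")
        if not 0 <= self.gamma < 1:
            raise ValueError("gamma must lie in [0, 1)")
        if self.gamma == 0:
            return np.full(p, self.lam)
        if self.base_importance is None:
            raise ValueError("gamma > 0 requires a base importance vector")
        imp = np.clip(np.asarray(self.base_importance, dtype=float), 0.0, None)
        if len(imp) != p:
            raise ValueError("base_importance length must equal number of loci")
        top = imp.max()
        norm = imp / top if top > 0 else np.zeros(p)
        return (1.0 - self.gamma) * self.lam + self.gamma * norm


class _Tree:
    """A grown binary tree in flat-array form."""

    __slots__ = ("feature", "thr", "left", "right", "leaf", "oob")

    def __init__(self, feature, thr, left, right, leaf, oob):
        self.feature = np.asarray(feature, dtype=np.int32)
        self.thr = np.asarray(thr, dtype=np.float64)
        self.left = np.asarray(left, dtype=np.int32)
        self.right = np.asarray(right, dtype=np.int32)
        self.leaf = np.asarray(leaf, dtype=np.int32)
        self.oob = oob  # indices of out-of-bag training cases

    def predict(self, X: np.ndarray) -> np.ndarray:
        n = X.shape[0]
        node = np.zeros(n, dtype=np.int32)
        out = np.empty(n, dtype=np.int32)
        active = np.arange(n)
        while active.size:
            nd = node[active]
            at_leaf = self.leaf[nd] >= 0
            out[active[at_leaf]] = self.leaf[nd[at_leaf]]
            active = active[~at_leaf]
            if not active.size:
                break
            nd = node[active]
            go_left = X[active, self.feature[nd]] < self.thr[nd]
            node[active] = np.where(go_left, self.left[nd], self.right[nd])
        return out

    def used_features(self) -> np.ndarray:
        return np.unique(self.feature[self.leaf < 0])


@dataclass
class Forest:
    """A grown forest plus its out-of-bag diagnostics."""

    trees: list
    classes: list
    oob_error: float
    config: ForestConfig
    locus_ids: list = field(default_factory=list)

    def predict_codes(self, X: np.ndarray) -> np.ndarray:
        votes = np.zeros((X.shape[0], len(self.classes)), dtype=np.int32)
        for t in self.trees:
            votes[np.arange(X.shape[0]), t.predict(X)] += 1
        return votes.argmax(axis=1)  # plurality; tie -> lowest class label

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.classes, dtype=object)[self.predict_codes(X)]


def _as_xy(train, labels):
    if isinstance(train, GenotypeMatrix):
        X = train.dosages
        y_raw = train.populations if labels is None else np.asarray(labels)
        locus_ids = list(train.locus_ids)
    else:
        X = np.asarray(train, dtype=float)
        if labels is None:
            raise ValueError("labels required for an array input")
        y_raw = np.asarray(labels)
        locus_ids = [str(j) for j in range(X.shape[1])]
    if np.isnan(X).any():
        raise ValueError("forest input must have no missing cells (impute first)")
    classes = sorted(set(map(str, y_raw)))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if X.shape[1] == 0:
        raise ValueError("need at least 1 locus")
    code = {c: k for k, c in enumerate(classes)}
    y = np.array([code[str(v)] for v in y_raw], dtype=np.int32)
    return X, y, classes, locus_ids


def _best_split(A, B, onehot, idx, feats, parent_counts, penalty, in_f):
    """Return (raw_gain, feat, thr) of the winning split or None.

    Score = gain * penalty for loci outside the selected set, raw gain
    inside.  Ties prefer already-selected loci, then the lowest locus index,
    then the lower threshold.
    """
    n_node = idx.size
    Y = onehot[idx]
    left25 = A[idx][:, feats].T @ Y  # (mtry, K) class counts left of 0.25
    left75 = B[idx][:, feats].T @ Y
    sum_parent_sq = float((parent_counts.astype(float) ** 2).sum())
    base = sum_parent_sq / (n_node * n_node)

    best = None  # (neg criteria tuple ordering) -> track manually
    for thr_i, left in enumerate((left25, left75)):
        nL = left.sum(axis=1)
        right = parent_counts[None, :] - left
        nR = n_node - nL
        valid = (nL > 0) & (nR > 0)
        if not valid.any():
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            s = (left**2).sum(axis=1) / nL + (right**2).sum(axis=1) / nR
        gain = s / n_node - base
        gain[~valid] = -np.inf
        pen = penalty[feats].copy()
        pen[in_f[feats]] = 1.0
        score = gain * pen
        score[gain <= _GAIN_EPS] = -np.inf
        j = score.argmax()
        top = score[j]
        if top == -np.inf:
            continue
        ties = np.flatnonzero(score == top)
        # prefer selected loci, then lowest locus index
        tie_feats = feats[ties]
        sel = in_f[tie_feats]
        if sel.any():
            tie_feats = tie_feats[sel]
        f = tie_feats.min()
        g = gain[ties[np.flatnonzero(feats[ties] == f)[0]]]
        cand = (top, not in_f[f], f, thr_i, g)
        if best is None or (cand[0], -cand[1], -cand[2], -cand[3]) > (
            best[0], -best[1], -best[2], -best[3]
        ):
            best = cand
    if best is None:
        return None
    return best[4], best[2], _THRESHOLDS[best[3]]


def _grow_tree(X, A, B, onehot, y, rng, mtry, min_node, penalty, in_f, selected_order,
               locus_ids):
    n, p = X.shape
    boot = rng.integers(0, n, n)
    oob = np.setdiff1d(np.arange(n), boot)

    feature, thr, left, right, leaf = [], [], [], [], []

    def new_node():
        feature.append(-1)
        thr.append(0.0)
        left.append(-1)
        right.append(-1)
        leaf.append(-1)
        return len(feature) - 1

    def build(idx):
        me = new_node()
        counts = np.bincount(y[idx], minlength=onehot.shape[1])
        if idx.size <= min_node or (counts > 0).sum() == 1:
            leaf[me] = int(counts.argmax())  # argmax tie -> lowest class
            return me
        feats = rng.choice(p, size=mtry, replace=False)
        split = _best_split(A, B, onehot, idx, feats, counts, penalty, in_f)
        if split is None:
            leaf[me] = int(counts.argmax())
            return me
        gain, f, t = split
        if not in_f[f]:
            in_f[f] = True
            selected_order.append(locus_ids[f])
        go_left = X[idx, f] < t
        feature[me], thr[me] = f, t
        left[me] = build(idx[go_left])
        right[me] = build(idx[~go_left])
        return me

    build(boot)
    return _Tree(feature, thr, left, right, leaf, oob)


def _grow(train, labels, cfg: ForestConfig, reg: RegularizationParams | None):
    X, y, classes, locus_ids = _as_xy(train, labels)
    n, p = X.shape
    mtry = cfg.resolve_mtry(p)
    if cfg.ntree < 1 or cfg.min_node < 1:
        raise ValueError("ntree and min_node must be positive")
    rng = np.random.default_rng(cfg.seed)
    A = (X < _THRESHOLDS[0]).astype(np.float64)
    B = (X < _THRESHOLDS[1]).astype(np.float64)
    K = len(classes)
    onehot = np.zeros((n, K))
    onehot[np.arange(n), y] = 1.0

    penalty = np.ones(p) if reg is None else reg.penalties(p)
    in_f = np.zeros(p, dtype=bool) if reg is None else np.zeros(p, dtype=bool)
    if reg is None:
        in_f[:] = True  # plain forest: no penalty bookkeeping
    selected_order: list = []

    trees = []
    votes = np.zeros((n, K), dtype=np.int32)
    for _ in range(cfg.ntree):
        t = _grow_tree(X, A, B, onehot, y, rng, mtry, cfg.min_node, penalty,
                       in_f, selected_order, locus_ids)
        if t.oob.size:
            votes[t.oob, t.predict(X[t.oob])] += 1
        trees.append(t)

    covered = votes.sum(axis=1) > 0
    if covered.any():
        pred = votes.argmax(axis=1)
        oob_error = float((pred[covered] != y[covered]).mean())
    else:
        oob_error = np.nan
    forest = Forest(trees, classes, oob_error, cfg, locus_ids)
    return forest, selected_order, (X, y)


def grow_forest(train, labels=None, cfg: ForestConfig | None = None) -> Forest:
    """Grow a plain classification forest (bootstrap + Gini, no penalty)."""
    forest, _, _ = _grow(train, labels, cfg or ForestConfig(), None)
    return forest


def grow_regularized_forest(train, labels=None, cfg: ForestConfig | None = None,
                            reg: RegularizationParams | None = None):
    """Grow an RRF/GRRF forest; returns ``(forest, selected_locus_ids)``.

    Trees are grown sequentially so the selected set accumulates across the
    whole forest; the returned list is in order of first selection.
    """
    forest, selected, _ = _grow(train, labels, cfg or ForestConfig(),
                                reg or RegularizationParams())
    return forest, selected


def mda_importance(forest: Forest, train, labels=None, seed: int = 0,
                   scaled: bool = False) -> np.ndarray:
    """Permutation mean-decrease-in-accuracy per locus (raw by default).

    Per tree with at least one out-of-bag case: accuracy on the tree's OOB
    cases minus accuracy after permuting one locus among them, averaged over
    such trees.  Loci unused by a tree contribute exactly 0 for that tree,
    so a constant locus has MDA exactly 0.

    With ``scaled`` the mean is divided by its standard error over trees
    (the normalization some forest tools apply); loci with zero variance
    stay 0.
    """
    X, y, classes, _ = _as_xy(train, labels)
    if classes != forest.classes:
        raise ValueError("labels do not match the classes the forest was grown on")
    rng = np.random.default_rng(seed)
    p = X.shape[1]
    total = np.zeros(p)
    total_sq = np.zeros(p)
    n_trees_oob = 0
    for t in forest.trees:
        oob = t.oob
        if not oob.size:
            continue
        n_trees_oob += 1
        Xo = X[oob]
        yo = y[oob]
        acc0 = float((t.predict(Xo) == yo).mean())
        for f in t.used_features():
            perm = rng.permutation(oob.size)
            Xp = Xo.copy()
            Xp[:, f] = Xo[perm, f]
            acc = float((t.predict(Xp) == yo).mean())
            d = acc0 - acc
            total[f] += d
            total_sq[f] += d * d
    if n_trees_oob == 0:
        return np.zeros(p)
    mean = total / n_trees_oob
    if not scaled:
        return mean
    if n_trees_oob < 2:
        return mean
    var = (total_sq - n_trees_oob * mean**2) / (n_trees_oob - 1)
    se = np.sqrt(np.clip(var, 0.0, None) / n_trees_oob)
    out = np.zeros(p)
    nz = se > 0
    out[nz] = mean[nz] / se[nz]
    return out
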