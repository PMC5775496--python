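# Methods

This note records the models implemented in `panelforge`, the defaults and
why they were chosen, and what the synthetic data do and do not establish.

## Genotype representation

Diploid bi-allelic calls are dosage codes: 0 = homozygous for the minor
allele, 0.5 = heterozygous, 1 = homozygous for the major allele; NaN =
missing. The minor allele is defined **globally**, over all populations
pooled, with frequency ties at 0.5 broken to the lexicographically smaller
allele code. All producers in the package (the Genepop reader, the
simulator) emit this orientation, and the Weir–Cockerham estimator is
invariant to flipping it. Consequence worth knowing: the Genepop
writer/reader round-trips dosages and population labels exactly only while
the minor-coded allele is globally the rarer one — subsetting individuals
can in principle flip which allele is rarer, and a re-read re-orients.

## Quality control

The filter chain, in order:

1. **MAF**: drop loci with pooled minor-allele frequency < 0.05 over
   non-missing calls ("below 5%" read literally — exactly 0.05 is kept).
2. **Missingness**: drop loci missing in > 5% of individuals (again
   literal: exactly 5% is kept).
3. **Imputation** (forest proximity): missing cells start at the
   within-population per-locus mode; each round grows a classification
   forest predicting the population label, computes co-leaf proximities,
   and replaces each originally-missing cell with the proximity-weighted
   mean of the observed dosages at that locus, snapped to the nearest code.
   Defaults: 5000 trees, 5 rounds. The iteration count is a package choice
   (the proximity imputer this emulates has no stated convergence rule);
   observed cells are never altered, and at the sub-0.1% missingness this
   pipeline targets the result is insensitive to both knobs.
4. **Top-loci pruning**: a greedy scan in descending global-θ order keeps a
   locus iff θ ≥ 0.05 and its squared Pearson correlation of dosages
   (pairwise-complete individuals; a composite-LD proxy) with every
   already-kept locus is ≤ 0.2. Pairs with fewer than 10 complete
   individuals are treated as R² = 0. Greedy keep-best was chosen over any
   graph-optimal subset: it is deterministic, order-independent (the scan
   order is θ then locus id, never column position), and matches how
   "top loci" tools behave in practice.

## Weir–Cockerham F_ST

Per locus, the WC84 variance components a (among populations), b (among
individuals within populations) and c (within individuals) are computed
from per-population complete-case sample sizes, minor-allele frequencies
and observed heterozygote proportions; θ = a/(a+b+c). Multi-locus and
pairwise values are **ratios of summed components**, not means of per-locus
ratios. Negative estimates are reported as computed — clamping would bias
every downstream ranking. Monomorphic loci (a+b+c = 0) are undefined and
rank last; loci where fewer than two populations have data, or the mean
complete-case sample size is 1, are likewise undefined rather than zero.

## The forests

Written from scratch because the regularized variants need machinery no
stock implementation exposes: a per-feature penalty on split gain and a
selected-feature set shared across sequentially grown trees.

* Trees grow on bootstrap samples (n draws with replacement); each node
  samples `mtry` loci without replacement and takes the best
  Gini-gain split. Because dosages take only {0, 0.5, 1}, the only useful
  thresholds are 0.25 and 0.75, which makes node evaluation two small
  matrix products. Recursion stops at purity, at node size ≤ `min_node`,
  or when no sampled locus has positive gain. Leaves vote by in-bag
  majority (ties to the lowest class label); the forest predicts by
  plurality (same tie rule).
* Defaults: `ntree = 2000` (out-of-bag error stabilizes by then at this
  data scale), `mtry = 2·⌈√p⌉` (twice the square-root default, the setting
  that minimized error in the motivating comparisons), `min_node = 5`.
* **MDA importance** is the permutation mean decrease in accuracy: per tree
  with ≥ 1 out-of-bag case, OOB accuracy minus accuracy after permuting one
  locus among the OOB cases, averaged over such trees. Loci a tree never
  splits on contribute exactly 0 for that tree — so a constant locus has
  MDA exactly 0, and the computation only touches each tree's used loci.
  MDA is reported raw (not divided by a standard error): unscaled values
  are reproducible and scaling is a tool-specific option.
* **RRF/GRRF**: a growing selected set F starts empty; at a node the
  candidate score of locus i is gain·λ_i if i ∉ F and the raw gain if
  i ∈ F; the winner is split on and joins F. Trees grow **sequentially**
  so F accumulates across the forest (parallelism would change the
  algorithm). Per-feature penalty λ_i = (1−γ)·λ + γ·imp_i with λ ∈ (0,1],
  γ ∈ [0,1), and imp the guide importance clipped at 0 and divided by its
  maximum; γ = 0 gives plain RRF, and GRRF is run at λ = 1 so γ alone
  controls panel size. Tie-break on equal scores: already-selected loci
  first, then the lowest locus index, then the lower threshold. The
  selected-first rule matters — with a duplicated informative column at
  λ = 1, a lowest-index-only rule would let the second copy enter F
  whenever the higher-index copy was selected first; preferring F members
  keeps exact duplicates out, which is the point of the regularization.
* Determinism: one seeded PCG64 generator drives bootstraps, feature
  subsampling and MDA permutations; identical seed, config and data give
  bit-identical forests on any platform.

## Panel construction

All selection sees only a stratified training split: per population,
round-half-up(n/3) individuals (minimum 1), sampled without replacement
under the run seed. The rest are holdout.

* **FST panels**: top-k by global θ computed on training individuals only.
* **RF consensus**: five forest runs differing only by seed (seed,
  seed+1, …, seed+4) each yield an MDA ranking truncated to positive-MDA
  loci; the panel at rank level k is the intersection of the five top-k
  sets, ordered by mean rank (ties by locus id). The rank level for a
  target panel size is found from the consensus-size curve, which is
  non-decreasing in k; targets no level reaches within ±10% produce the
  closest achievable size and a warning.
* **RRF/GRRF panels** are whatever F the regularization emits — sizes
  cannot be dialled exactly, so comparisons pair each method's panel
  nearest the target and always report the realized size next to the
  accuracy.

## Assignment model

Genetic stock identification with a leave-one-out correction. The baseline
is per-population minor-allele counts over **all** individuals at the panel
loci. For an individual, its own two alleles per called locus are first
subtracted from its population's counts; each population k is then scored

    log L_k = Σ_loci log P(genotype | q_k),   q_k = (count + ½)/(total + 1)

with Hardy–Weinberg genotype probabilities q², 2q(1−q), (1−q)², a uniform
prior, and log-space accumulation (mandatory at several hundred loci).
Dirichlet(½, ½) smoothing is the model family underlying standard GSI
engines and keeps q strictly inside (0, 1) even after leave-one-out
subtraction. Missing calls are skipped symmetrically; an individual with no
called panel loci gets the uniform posterior. Argmax ties resolve to the
lowest population label. Headline accuracy uses holdout individuals only;
training-individual accuracy is exposed for diagnostics, and on synthetic
sweeps holdout accuracy stays within noise of (and below) training
accuracy, as the leave-one-out construction intends. A bootstrap
genotype simulator from baseline frequencies is provided for power checks;
it is not part of the headline accuracy path.

## Synthetic data

Balding–Nichols: per locus an ancestral minor-allele frequency p ~
Uniform(0.05, 0.5); each population's frequency is a
Beta(p(1−F)/F, (1−p)(1−F)/F) draw, giving across-population variance
p(1−p)F; individuals are Binomial(2, q) draws under Hardy–Weinberg. F = 0
degenerates to q = p exactly. An optional two-level hierarchy composes a
between-region and a within-region draw, splitting each locus's F between
levels in proportion to the configured between/within weights.

The default conditions emulate a low-differentiation salmonid SNP panel:
5 populations × 30 individuals, 2000 loci, 0.08% missing cells, and a
per-locus F mixture of 85% at F = 0.0429 and 15% at F = 0.15 (mean 0.059).
The mixture was calibrated once against the target shape of the per-locus
global θ distribution — mean ≈ 0.059 with a maximum around 0.6 — across
many seeds; heavier top components (F ≥ 0.25) realize θ near 1 at these
sample sizes and were rejected. Loci are re-oriented after simulation so
the minor-coded allele is globally the rarer one (`reorient=False` keeps
the raw orientation; the re-orientation is why a locus simulated at minor
frequency 1 emerges as all-major dosage 1).

What the generator does **not** model: linkage between loci, sibling/family
structure, migration, selection, genotyping batch effects. Passing tests on
this generator therefore demonstrate correctness of the estimators and the
selection/assignment machinery under the assumed statistical structure, not
performance on any particular real data set. Under the default conditions
the assignment problem is in fact easy (holdout accuracy saturates near
100% with ~100-locus panels); the harder regimes in the README example
(more populations, uniform low F) are where the selection methods separate.

## Evaluation

Accuracy-vs-size tables carry one row per (method, parameter) with overall
and per-population holdout accuracy. The method-effect test is a nested OLS
comparison — accuracy ~ size + size² against accuracy ~ size + size² +
method — reporting the F statistic with its own degrees of freedom (the
historical F(28,37) layout of the motivating analysis is not recoverable
from its description, so the plain nested ANOVA is the implemented
meaning). Confusion matrices are row-normalized percentages over holdout
individuals. The mismatch-delta table pairs each population pair's
multi-locus θ with the difference in cross-assignment proportion between
two methods' results on the same split. Plots are left to the caller:
every figure-shaped output is emitted as a table, because numbers, not
pixels, are the testable surface.

## Problem sizes used by the test suite and acceptance script

Chosen so a full run fits comfortably on one CPU: forests of 200–500 trees
for selection experiments (panel-size monotonicity and MDA enrichment are
stable well before 2000 trees at p ≤ 2000), an imputer of 300 trees × 2
rounds inside the end-to-end studies (at 0.08% missingness the imputed
cells are determined by the population mode long before proximity
refinement), and three seeds for every stochastic claim. The spec-level
defaults (2000 trees, 5000-tree imputer) remain the package defaults.

## Known limitations

* RRF/GRRF panel size is an emergent quantity; matching a target size
  exactly is not possible, only nearest-size pairing.
* The forest is exact but not optimized for very large p (≫ 10⁴ loci);
  growing is O(ntree · nodes · mtry · n).
* Negative multi-locus θ between near-identical populations is expected
  estimator behaviour, not an error.
* With fewer than ~10 pairwise-complete individuals, LD pruning treats a
  locus pair as uncorrelated; extremely sparse data can therefore retain
  correlated pairs.
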