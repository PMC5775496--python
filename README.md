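# panelforge

SNP panel selection and fine-scale genetic population assignment.

Fisheries management and conservation genetics often need to assign an
individual fish back to its natal river from a small, affordable panel of
SNPs. With thousands of candidate loci and weak differentiation among
neighbouring populations (global F<sub>ST</sub> on the order of 0.05), the
question is *which* subset of loci to genotype. `panelforge` implements and
compares four selection strategies on dosage-coded diploid genotypes:

* **F<sub>ST</sub> rank** — top loci by per-locus global Weir–Cockerham θ,
* **RF** — consensus of five random-forest runs ranked by permutation
  importance (mean decrease in accuracy, MDA),
* **RRF** — a regularized forest whose split gain for a locus *i* not yet
  in the selected set *F* is penalized by λ ∈ (0, 1]; the loci that win
  splits form the panel,
* **GRRF** — the guided variant, with per-locus penalty
  λ<sub>i</sub> = (1 − γ)λ + γ·imp<sub>i</sub>, where imp is a prior MDA
  vector normalized to [0, 1]; larger γ yields a smaller panel.

Panels are scored by **leave-one-out self-assignment**: baseline allele
counts come from *all* individuals, but only a one-third training subset
selects the loci, and only the holdout individuals count toward accuracy —
the combination that keeps self-assignment estimates free of high-grading
bias. The assignment likelihood is Hardy–Weinberg with Dirichlet(½, ½)
smoothed frequencies q = (count + ½)/(total + 1), accumulated in log space
with a uniform prior over populations.

A Balding–Nichols synthetic-data generator (population frequencies drawn
from Beta(p(1−F)/F, (1−p)(1−F)/F) around ancestral frequencies p)
reproduces the statistical structure of a low-differentiation salmonid SNP
panel, so the whole pipeline is testable without any external data.

## Worked example

Eight weakly differentiated populations (uniform simulated F = 0.03, 20
individuals each, 1000 loci), four panels built from the training third at
a matched target of ~50 loci:

```python
import panelforge as pf
from panelforge.pipeline import run_study

cfg = pf.SimConfig(n_pops=8, n_per_pop=20, n_loci=1000,
                   fst_mix=((1.0, 0.03),), missing_rate=0.0008, seed=42)
run = run_study(42, sim_cfg=cfg,
                filter_cfg=pf.FilterConfig(fst_min=0.02, impute_trees=300,
                                           impute_iters=2, seed=42),
                target_size=50)
print(run.summary().to_string(index=False))
```

```
method  parameter  size  holdout_accuracy  training_accuracy
   FST       50.0    50         62.500000          91.071429
    RF      229.0    50         75.961538          87.500000
   RRF        0.1    88         85.576923          94.642857
  GRRF        0.9   106         88.461538         100.000000
```

Reading the table: the F<sub>ST</sub>-ranked 50-locus panel assigns 62.5%
of holdout individuals to the correct population, while forest-based
selection reaches 76–88% at comparable size — the regularized variants emit
whatever their penalty selects (88 and 106 loci here), so sizes are
reported next to accuracies. The gap between training and holdout accuracy
is exactly the high-grading bias the training/holdout + leave-one-out
design exists to control; only the holdout column is the honest estimate.

The same workflow is scriptable from the shell:

```bash
panelforge simulate --pops 5 --n 30 --loci 2000 --seed 7 --out sim.tsv
panelforge filter   --in sim.tsv --out filtered.tsv --seed 7
panelforge panels   --in filtered.tsv --method grrf \
                    --params 0.25,0.1,0.01 --seed 7 --out-dir panels/
panelforge assign   --in filtered.tsv --panel panels/GRRF_0.25.txt \
                    --split panels/split.json --out results.tsv
panelforge pipeline --seed 7 --target-size 100 --out-dir study/
```

Genepop files are read and written natively (`panelforge convert`), so
panels can be built for existing data sets.

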