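from fractions import Fraction

import numpy as np
import pytest

import panelforge as pf
from panelforge.assign import Baseline

from _oracles import loo_posterior_oracle
from conftest import random_matrix


def _hand_posterior_het_one_locus():
    """Two populations, one locus, counts 9/20 and 1/20; a heterozygote not
    in the baseline.  Exact value by rational arithmetic."""
    q1 = Fraction(9 * 2 + 1, 2) / 21  # (9 + .5)/21 as a fraction = 19/42
    q2 = Fraction(3, 2) / 21
    l1 = 2 * q1 * (1 - q1)
    l2 = 2 * q2 * (1 - q2)
    return float(l1 / (l1 + l2))


class TestBuildBaseline:
    def test_hand_counts(self):
        # dosage 0 carries 2 minor alleles, 0.5 carries 1
        m = pf.GenotypeMatrix(["a", "b"], ["A", "A"], ["L"], [[0.0], [0.5]])
        b = pf.build_baseline(m, ["L"])
        assert b.minor_counts[0, 0] == 3
        assert b.totals[0, 0] == 4

    def test_missing_contributes_nothing(self):
        m = pf.GenotypeMatrix(["a", "b"], ["A", "A"], ["L"],
                              [[0.0], [np.nan]])
        b = pf.build_baseline(m, ["L"])
        assert b.minor_counts[0, 0] == 2
        assert b.totals[0, 0] == 2

    def test_empty_panel_allowed(self, rng):
        b = pf.build_baseline(random_matrix(rng), [])
        assert b.minor_counts.shape[1] == 0

    def test_population_without_calls_rejected(self):
        m = pf.GenotypeMatrix(["a", "b"], ["A", "B"], ["L"],
                              [[0.0], [np.nan]])
        with pytest.raises(ValueError, match="B"):
            pf.build_baseline(m, ["L"])

    def test_count_invariant_enforced(self):
        with pytest.raises(ValueError, match="count"):
            Baseline(["A"], ["L"], [[5.0]], [[4.0]])


class TestLooPosterior:
    def test_hand_computed_two_pop_case(self):
        # baseline pops: A with 9 minor of 20 alleles, B with 1 of 20
        d_a = [[0.0]] * 4 + [[0.5]] + [[1.0]] * 5        # 9 minor / 20
        d_b = [[0.5]] + [[1.0]] * 9                       # 1 minor / 20
        m_base = pf.GenotypeMatrix(
            [f"A{i}" for i in range(10)] + [f"B{i}" for i in range(10)],
            ["A"] * 10 + ["B"] * 10, ["L"], np.vstack([d_a, d_b]))
        baseline = pf.build_baseline(m_base, ["L"])
        m_test = pf.GenotypeMatrix(["x"], ["A"], ["L"], [[0.5]])
        post = pf.loo_posterior("x", m_test, baseline, leave_out=False)
        assert post[0] == pytest.approx(_hand_posterior_het_one_locus(),
                                        abs=1e-12)

    def test_single_population_posterior_is_one(self):
        m = pf.GenotypeMatrix(["a", "b"], ["A", "A"], ["L"], [[0.0], [1.0]])
        b = pf.build_baseline(m, ["L"])
        post = pf.loo_posterior("a", m, b)
        np.testing.assert_array_equal(post, [1.0])

    def test_identical_baselines_split_evenly(self):
        block = [[0.0], [0.5], [1.0], [1.0]]
        m = pf.GenotypeMatrix(
            [f"A{i}" for i in range(4)] + [f"B{i}" for i in range(4)],
            ["A"] * 4 + ["B"] * 4, ["L"], np.vstack([block, block]))
        b = pf.build_baseline(m, ["L"])
        m_test = pf.GenotypeMatrix(["x"], ["A"], ["L"], [[0.5]])
        post = pf.loo_posterior("x", m_test, b, leave_out=False)
        np.testing.assert_allclose(post, [0.5, 0.5], atol=1e-15)

    def test_foreign_baseline_breach_detected(self, rng):
        m1 = random_matrix(rng, n_pops=2, n_per_pop=5, n_loci=4)
        empty = pf.GenotypeMatrix(
            m1.individual_ids, m1.populations, m1.locus_ids,
            np.full_like(m1.dosages, 1.0))
        b = pf.build_baseline(empty, list(m1.locus_ids))
        # m1 has minor alleles the all-major baseline never counted
        assert (m1.dosages < 1).any()
        with pytest.raises(RuntimeError, match="negative"):
            for ind in m1.individual_ids:
                pf.loo_posterior(ind, m1, b)


class TestSelfAssign:
    def test_separable_fixture_fully_correct(self):
        m, manifest = pf.make_fixture("tiny_separable")
        split = pf.training_split(m, 1 / 3, seed=1)
        res = pf.self_assign(m, list(m.locus_ids), split)
        acc, per_pop = pf.accuracy_summary(res)
        assert acc == manifest["expected_holdout_accuracy"]
        assert (per_pop == 100.0).all()

    def test_empty_panel_uniform_posteriors(self, rng):
        m = random_matrix(rng, n_pops=4, n_per_pop=10)
        res = pf.self_assign(m, [])
        post_cols = [c for c in res.columns if c.startswith("post_")]
        np.testing.assert_allclose(res[post_cols].to_numpy(), 0.25)

    def test_posteriors_sum_to_one(self, rng):
        m = random_matrix(rng, n_pops=3, n_per_pop=12, n_loci=40,
                          missing_rate=0.05)
        res = pf.self_assign(m, list(m.locus_ids))
        post_cols = [c for c in res.columns if c.startswith("post_")]
        np.testing.assert_allclose(res[post_cols].sum(axis=1), 1.0,
                                   atol=1e-12)

    def test_all_missing_individual_gets_uniform(self):
        d = np.array([[0.0, 1.0], [1.0, 0.0], [np.nan, np.nan], [0.5, 0.5]])
        m = pf.GenotypeMatrix(["a", "b", "c", "d"], ["A", "A", "B", "B"],
                              ["L1", "L2"], d)
        res = pf.self_assign(m, ["L1", "L2"])
        row = res[res["individual"] == "c"].iloc[0]
        assert row["post_A"] == pytest.approx(0.5)

    def test_matches_scalar_oracle(self, rng):
        m = random_matrix(rng, n_pops=3, n_per_pop=10, n_loci=25,
                          missing_rate=0.03)
        res = pf.self_assign(m, list(m.locus_ids))
        b = pf.build_baseline(m, list(m.locus_ids))
        pops = b.populations
        minor = {p: list(b.minor_counts[k]) for k, p in enumerate(pops)}
        total = {p: list(b.totals[k]) for k, p in enumerate(pops)}
        sub = m.subset_loci(b.locus_ids)
        for i in rng.choice(m.n_individuals, 8, replace=False):
            want = loo_posterior_oracle(
                list(sub.dosages[i]), str(m.populations[i]), minor, total, pops)
            got = res.iloc[i][[f"post_{p}" for p in pops]].to_numpy(float)
            np.testing.assert_allclose(got, want, atol=1e-10)

    def test_shuffled_labels_near_chance(self):
        m, manifest = pf.make_fixture("null_shuffled")
        split = pf.training_split(m, 1 / 3, seed=3)
        res = pf.self_assign(m, list(m.locus_ids), split)
        acc, _ = pf.accuracy_summary(res)
        assert abs(acc - manifest["expected_accuracy_about"]) <= 20


class TestAccuracyVsDifferentiation:
    def test_holdout_accuracy_nondecreasing_in_simulated_fst(self):
        accs = []
        for F in (0.01, 0.05, 0.10, 0.20):
            cfg = pf.SimConfig(n_pops=4, n_per_pop=25, n_loci=300,
                               fst_mix=((1.0, F),), missing_rate=0.0, seed=60)
            m, _ = pf.simulate(cfg)
            split = pf.training_split(m, 1 / 3, seed=60)
            train = m.subset_individuals(~split.is_holdout(m.individual_ids))
            panel = pf.fst_rank_panel(pf.locus_stats(train), 50)
            acc, _ = pf.accuracy_summary(pf.self_assign(m, panel, split))
            accs.append(acc)
        for lo, hi in zip(accs, accs[1:]):
            assert hi >= lo - 2.0  # monotone up to noise


class TestAccuracySummary:
    def test_arithmetic(self):
        import pandas as pd
        res = pd.DataFrame({
            "true_pop": ["A"] * 10 + ["B"] * 10,
            "assigned_pop": ["A"] * 9 + ["B"] + ["B"] * 10,
            "holdout": [True] * 20,
        })
        overall, per_pop = pf.accuracy_summary(res)
        assert overall == 95.0
        assert per_pop["A"] == 90.0 and per_pop["B"] == 100.0

    def test_empty_holdout_rejected(self):
        import pandas as pd
        res = pd.DataFrame({"true_pop": ["A"], "assigned_pop": ["A"],
                            "holdout": [False]})
        with pytest.raises(ValueError, match="holdout"):
            pf.accuracy_summary(res)


class TestSimulateBaselineGenotypes:
    def test_fixed_frequencies_give_fixed_genotypes(self):
        b = Baseline(["A", "B"], ["L1", "L2"],
                     [[20.0, 0.0], [0.0, 20.0]],
                     [[20.0, 20.0], [20.0, 20.0]])
        sim = pf.simulate_baseline_genotypes(b, 5, seed=1, smoothed=False)
        d = sim.dosages
        np.testing.assert_array_equal(d[sim.populations == "A", 0], 0.0)
        np.testing.assert_array_equal(d[sim.populations == "A", 1], 1.0)

    def test_large_sample_recovers_frequencies(self, rng):
        m = random_matrix(rng, n_pops=2, n_per_pop=20, n_loci=30)
        b = pf.build_baseline(m, list(m.locus_ids))
        sim = pf.simulate_baseline_genotypes(b, 4000, seed=2)
        q = b.frequencies()
        for k, pop in enumerate(b.populations):
            realized = np.mean(1.0 - sim.dosages[sim.populations == pop], axis=0)
            assert np.abs(realized - q[k]).max() <= 0.02

    def test_seeded_determinism(self, rng):
        m = random_matrix(rng)
        b = pf.build_baseline(m, list(m.locus_ids))
        s1 = pf.simulate_baseline_genotypes(b, 10, seed=3)
        s2 = pf.simulate_baseline_genotypes(b, 10, seed=3)
        np.testing.assert_array_equal(s1.dosages, s2.dosages)
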