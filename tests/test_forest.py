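import numpy as np
import pytest

import panelforge as pf
from panelforge.forest import RegularizationParams

from conftest import random_matrix


def separable_matrix(n_per=20, noise_loci=3, seed=0):
    """Two populations split perfectly by locus L1."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per
    d = rng.choice([0.0, 0.5, 1.0], size=(n, noise_loci + 1))
    d[:n_per, 0] = 0.0
    d[n_per:, 0] = 1.0
    return pf.GenotypeMatrix(
        [f"i{k}" for k in range(n)],
        ["A"] * n_per + ["B"] * n_per,
        [f"L{j + 1}" for j in range(noise_loci + 1)],
        d,
    )


class TestGrowForest:
    def test_separable_fixture_low_oob_error(self):
        m = separable_matrix(n_per=20)
        f = pf.grow_forest(m, cfg=pf.ForestConfig(ntree=100, seed=1))
        assert f.oob_error <= 0.05

    def test_shuffled_labels_oob_near_chance(self, rng):
        m = random_matrix(rng, n_pops=2, n_per_pop=25, n_loci=30)
        labels = np.array(m.populations)
        rng.shuffle(labels)
        f = pf.grow_forest(m.dosages, labels, pf.ForestConfig(ntree=200, seed=2))
        assert abs(f.oob_error - 0.5) <= 0.1

    def test_single_tree(self, rng):
        m = random_matrix(rng)
        f = pf.grow_forest(m, cfg=pf.ForestConfig(ntree=1, seed=3))
        assert len(f.trees) == 1

    def test_deterministic_given_seed(self, rng):
        m = random_matrix(rng, n_loci=20)
        cfg = pf.ForestConfig(ntree=30, seed=9)
        f1 = pf.grow_forest(m, cfg=cfg)
        f2 = pf.grow_forest(m, cfg=cfg)
        assert f1.oob_error == f2.oob_error
        for t1, t2 in zip(f1.trees, f2.trees):
            np.testing.assert_array_equal(t1.feature, t2.feature)
            np.testing.assert_array_equal(t1.thr, t2.thr)
            np.testing.assert_array_equal(t1.leaf, t2.leaf)
        np.testing.assert_array_equal(
            pf.mda_importance(f1, m, seed=9), pf.mda_importance(f2, m, seed=9)
        )

    def test_single_class_rejected(self):
        m = separable_matrix()
        with pytest.raises(ValueError, match="class"):
            pf.grow_forest(m.dosages, ["A"] * m.n_individuals)

    def test_zero_loci_rejected(self):
        with pytest.raises(ValueError, match="locus"):
            pf.grow_forest(np.empty((10, 0)), ["A"] * 5 + ["B"] * 5)

    def test_missing_cells_rejected(self, rng):
        m = random_matrix(rng, missing_rate=0.1)
        with pytest.raises(ValueError, match="missing"):
            pf.grow_forest(m)

    def test_matches_sklearn_on_separable_fixture(self):
        from sklearn.ensemble import RandomForestClassifier

        m = separable_matrix(n_per=25, noise_loci=5)
        ours = pf.grow_forest(m, cfg=pf.ForestConfig(ntree=100, seed=4))
        skl = RandomForestClassifier(n_estimators=100, random_state=4).fit(
            m.dosages, m.populations.astype(str)
        )
        grid = np.tile([0.0, 0.5, 1.0, 0.5, 1.0, 0.0], (6, 1)).astype(float)
        grid[:, 0] = [0, 0, 0, 1, 1, 1]
        np.testing.assert_array_equal(ours.predict(grid), skl.predict(grid))

    def test_oob_error_decreases_with_informative_loci(self):
        errs = []
        for n_inf in (0, 10, 50):
            frac = n_inf / 200
            mix = ((1.0, 0.005),) if n_inf == 0 else \
                ((frac, 0.3), (1 - frac, 0.005))
            cfg = pf.SimConfig(n_pops=3, n_per_pop=20, n_loci=200,
                               fst_mix=mix, missing_rate=0.0, seed=31)
            m, _ = pf.simulate(cfg)
            f = pf.grow_forest(m, cfg=pf.ForestConfig(ntree=200, seed=31))
            errs.append(f.oob_error)
        assert errs[1] <= errs[0] + 0.02
        assert errs[2] <= errs[1] + 0.02


class TestMdaImportance:
    def test_constant_locus_exactly_zero(self):
        m = separable_matrix()
        d = m.dosages.copy()
        d[:, 2] = 0.5
        f = pf.grow_forest(d, m.populations, pf.ForestConfig(ntree=50, seed=5))
        mda = pf.mda_importance(f, d, m.populations, seed=5)
        assert mda[2] == 0.0

    def test_planted_signal_is_argmax(self, rng):
        rngl = np.random.default_rng(17)
        n = 40
        d = rngl.choice([0.0, 0.5, 1.0], size=(n, 51))
        d[:20, 7] = 0.0
        d[20:, 7] = 1.0  # locus 7 fully determines the class
        labels = ["A"] * 20 + ["B"] * 20
        f = pf.grow_forest(d, labels, pf.ForestConfig(ntree=200, seed=6))
        mda = pf.mda_importance(f, d, labels, seed=6)
        assert int(np.argmax(mda)) == 7

    def test_scaled_mda_preserves_zero_and_sign(self):
        m = separable_matrix(n_per=20, noise_loci=5, seed=9)
        d = m.dosages.copy()
        d[:, 2] = 0.5  # constant
        f = pf.grow_forest(d, m.populations, pf.ForestConfig(ntree=100, seed=9))
        raw = pf.mda_importance(f, d, m.populations, seed=9)
        z = pf.mda_importance(f, d, m.populations, seed=9, scaled=True)
        assert z[2] == 0.0
        assert np.sign(z[0]) == np.sign(raw[0]) == 1.0
        assert int(np.argmax(z)) == 0  # the separating locus still leads

    def test_null_locus_mda_near_zero(self):
        m = separable_matrix(n_per=25, noise_loci=50, seed=8)
        f = pf.grow_forest(m, cfg=pf.ForestConfig(ntree=500, seed=8))
        mda = pf.mda_importance(f, m, seed=8)
        assert np.abs(mda[1:]).max() <= 0.01


class TestRegularizedForest:
    def test_duplicate_locus_enters_once(self):
        m = separable_matrix(n_per=20, noise_loci=2, seed=10)
        d = np.column_stack([m.dosages, m.dosages[:, 0]])  # copy of L1
        _, sel = pf.grow_regularized_forest(
            d, m.populations, pf.ForestConfig(ntree=50, seed=10),
            RegularizationParams(lam=1.0, gamma=0.0),
        )
        assert not ({"0", str(d.shape[1] - 1)} <= set(sel))

    def test_smaller_lambda_smaller_panel(self, rng):
        cfg = pf.SimConfig(n_pops=3, n_per_pop=15, n_loci=150,
                           fst_mix=((0.2, 0.2), (0.8, 0.02)),
                           missing_rate=0.0, seed=12)
        m, _ = pf.simulate(cfg)
        fcfg = pf.ForestConfig(ntree=100, seed=12)
        _, small = pf.grow_regularized_forest(m, cfg=fcfg,
                                              reg=RegularizationParams(lam=0.1))
        _, large = pf.grow_regularized_forest(m, cfg=fcfg,
                                              reg=RegularizationParams(lam=0.9))
        assert len(small) <= len(large)

    def test_larger_gamma_smaller_panel(self):
        cfg = pf.SimConfig(n_pops=3, n_per_pop=15, n_loci=150,
                           fst_mix=((0.2, 0.2), (0.8, 0.02)),
                           missing_rate=0.0, seed=13)
        m, _ = pf.simulate(cfg)
        fcfg = pf.ForestConfig(ntree=100, seed=13)
        guide = pf.grow_forest(m, cfg=fcfg)
        base = pf.mda_importance(guide, m, seed=13)
        _, strong = pf.grow_regularized_forest(
            m, cfg=fcfg, reg=RegularizationParams(1.0, 0.25, base))
        _, weak = pf.grow_regularized_forest(
            m, cfg=fcfg, reg=RegularizationParams(1.0, 0.01, base))
        assert len(strong) <= len(weak)

    def test_gamma_without_guide_rejected(self, rng):
        m = random_matrix(rng)
        with pytest.raises(ValueError, match="importance"):
            pf.grow_regularized_forest(m, reg=RegularizationParams(1.0, 0.2))

    def test_selected_set_is_split_loci(self, rng):
        m = random_matrix(rng, n_loci=40)
        f, sel = pf.grow_regularized_forest(
            m, cfg=pf.ForestConfig(ntree=30, seed=14),
            reg=RegularizationParams(lam=0.8),
        )
        used = set()
        for t in f.trees:
            used |= {str(m.locus_ids[j]) for j in t.used_features()}
        assert set(sel) == used

    def test_penalty_vector_bounds(self):
        base = np.array([0.5, -0.1, 2.0, 0.0])
        pen = RegularizationParams(0.7, 0.3, base).penalties(4)
        assert ((pen > 0) & (pen <= 1)).all()
        # max-importance locus gets the weakest penalty
        assert pen.argmax() == 2
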