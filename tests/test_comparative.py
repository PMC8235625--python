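import numpy as np
import pytest
from scipy import stats

import callimorph as cm
from callimorph.comparative import RetainedPCs
from callimorph.trees import star_tree


def blomberg_k_oracle(labels, C, y):
    """Direct transcription of the K formula with generic linear algebra,
    written independently of the package's vectorized path."""
    n = len(y)
    Cinv = np.linalg.inv(C)
    one = np.ones(n)
    a_hat = (one @ Cinv @ y) / (one @ Cinv @ one)
    r = y - a_hat
    observed = (r @ r) / (r @ Cinv @ r)
    expected = (np.trace(C) - n / (one @ Cinv @ one)) / (n - 1)
    return observed / expected


@pytest.fixture(scope="module")
def oracle_tree():
    return cm.PhyloTree.from_newick(
        "(((A:1,B:1):1.5,(C:2,D:0.5):0.5):2,((E:1.2,F:1.2):2,(G:2.2,H:2.2):1):1.3);"
    )


ORACLE_TRAIT = dict(A=1.21, B=0.84, C=-0.52, D=-1.13, E=0.33, F=0.17, G=-0.76, H=1.49)


class TestBlombergK:
    def test_star_tree_k_is_one_exactly(self, rng):
        st = star_tree(12, 2.0)
        trait = dict(zip(st.tip_labels, rng.normal(size=12)))
        assert cm.blomberg_k(st, trait, n_perm=10, seed=0).statistic == pytest.approx(1.0, abs=1e-12)

    def test_matches_direct_formula_oracle(self, oracle_tree):
        labels, C = oracle_tree.vcv()
        y = np.array([ORACLE_TRAIT[l] for l in labels])
        res = cm.blomberg_k(oracle_tree, ORACLE_TRAIT, n_perm=10, seed=0)
        assert res.statistic == pytest.approx(blomberg_k_oracle(labels, C, y), rel=1e-12)

    def test_matches_reference_implementation_value(self, oracle_tree):
        # frozen value computed once with an independent reference
        # implementation of phylogenetic signal (phytools::phylosig)
        res = cm.blomberg_k(oracle_tree, ORACLE_TRAIT, n_perm=10, seed=0)
        assert res.statistic == pytest.approx(0.666604292331, abs=1e-9)

    def test_invariances(self, oracle_tree):
        base = cm.blomberg_k(oracle_tree, ORACLE_TRAIT, n_perm=10, seed=0).statistic
        shifted = {k: v + 100.0 for k, v in ORACLE_TRAIT.items()}
        assert cm.blomberg_k(oracle_tree, shifted, n_perm=10, seed=0).statistic == pytest.approx(base, rel=1e-9)
        t = oracle_tree.copy()
        for e in t.dendropy_tree.preorder_edge_iter():
            if e.length is not None:
                e.length *= 7.0
        assert cm.blomberg_k(t, ORACLE_TRAIT, n_perm=10, seed=0).statistic == pytest.approx(base, rel=1e-9)

    def test_constant_trait_rejected(self, oracle_tree):
        with pytest.raises(ValueError, match="constant"):
            cm.blomberg_k(oracle_tree, {k: 1.0 for k in ORACLE_TRAIT}, n_perm=10, seed=0)

    def test_permutation_p_in_unit_interval_and_addone(self, oracle_tree):
        res = cm.blomberg_k(oracle_tree, ORACLE_TRAIT, n_perm=99, seed=3)
        assert 0 < res.p_value <= 1
        assert (res.p_value * 100) == pytest.approx(round(res.p_value * 100))


class TestKmult:
    def test_one_dimensional_reduces_to_k(self, oracle_tree):
        k1 = cm.blomberg_k(oracle_tree, ORACLE_TRAIT, n_perm=5, seed=0).statistic
        shapes = {k: np.array([v]) for k, v in ORACLE_TRAIT.items()}
        k2 = cm.k_mult(oracle_tree, shapes, n_perm=5, seed=0).statistic
        assert k1 == pytest.approx(k2, abs=1e-10)

    def test_star_tree_kmult_is_one(self, rng):
        st = star_tree(10, 1.5)
        shapes = {l: rng.normal(size=6) for l in st.tip_labels}
        assert cm.k_mult(st, shapes, n_perm=5, seed=0).statistic == pytest.approx(1.0, abs=1e-12)

    def test_brownian_calibration_small(self, rng):
        """Mean Kmult over Brownian simulations is near 1 (full-scale
        calibration is in the acceptance suite)."""
        t = cm.pure_birth_tree(20, seed=6)
        labels, C = t.vcv()
        L = np.linalg.cholesky(C)
        vals = []
        for _ in range(60):
            Y = L @ rng.standard_normal((20, 4))
            vals.append(cm.k_mult(t, dict(zip(labels, Y)), n_perm=1, seed=0).statistic)
        assert 0.8 < np.mean(vals) < 1.2


class TestPhylAnova:
    def test_star_tree_matches_standard_anova(self, rng):
        st = star_tree(20, 1.0)
        labels = st.tip_labels
        groups = {l: ("a" if i < 10 else "b") for i, l in enumerate(labels)}
        trait = dict(zip(labels, rng.normal(size=20)))
        res = cm.phyl_anova(st, groups, trait, n_sim=2000, seed=0)
        assert abs(res.p_phylo - res.p_standard) < 0.05

    def test_huge_effect_detected(self, rng):
        t = cm.pure_birth_tree(16, seed=2)
        labels = sorted(t.tip_labels)
        groups = {l: ("a" if i % 2 == 0 else "b") for i, l in enumerate(labels)}
        sd = np.sqrt(t.max_depth())
        trait = {l: rng.normal(0, 1) + (10 * sd if groups[l] == "a" else 0) for l in labels}
        res = cm.phyl_anova(t, groups, trait, n_sim=500, seed=0)
        assert res.p_phylo < 0.01

    def test_single_group_rejected(self, rng):
        t = cm.pure_birth_tree(8, seed=1)
        trait = dict(zip(t.tip_labels, rng.normal(size=8)))
        with pytest.raises(ValueError):
            cm.phyl_anova(t, {l: "a" for l in t.tip_labels}, trait)


class TestSizeComparison:
    def test_equal_group_means_not_significant(self, rng):
        st = star_tree(30, 1.0)
        labels = st.tip_labels
        groups = {l: ("VCL" if i < 15 else "HL") for i, l in enumerate(labels)}
        y = rng.normal(size=15)
        log_cs = dict(zip(labels, np.concatenate([y, y])))  # duplicated values
        out = cm.size_comparison(log_cs, groups, st, n_sim=200, seed=0)
        assert out["t_test_p"] > 0.99

    def test_shift_on_star_detected_by_both(self, rng):
        st = star_tree(30, 1.0)
        labels = st.tip_labels
        groups = {l: ("VCL" if i < 15 else "HL") for i, l in enumerate(labels)}
        log_cs = {l: rng.normal(0, 0.3) + (3 if groups[l] == "VCL" else 0) for l in labels}
        out = cm.size_comparison(log_cs, groups, st, n_sim=500, seed=0)
        assert out["t_test_p"] < 0.01
        assert out["phyl_anova_p"] < 0.01


class TestRetainPCs:
    def test_rank_one_data(self, rng):
        v = rng.normal(size=8)
        X = np.outer(rng.normal(size=10), v)
        out = cm.retain_pcs(X, 0.95)
        assert out.n_axes == 1

    def test_isotropic_3d_needs_all_axes(self, rng):
        X = rng.normal(size=(500, 3))
        assert cm.retain_pcs(X, 0.95).n_axes == 3

    def test_synthetic_spectrum(self, rng):
        """Variances {0.5, 0.3, 0.15, 0.05}: the 95% threshold is reached at
        exactly 3 axes."""
        n = 100
        var = np.array([0.5, 0.3, 0.15, 0.05])
        # construct data whose sample spectrum is exactly `var`
        G = rng.standard_normal((n, 4))
        U, _, _ = np.linalg.svd(G - G.mean(0), full_matrices=False)
        X = U @ np.diag(np.sqrt((n - 1) * var))
        out = cm.retain_pcs(X, 0.95)
        assert out.n_axes == 3
        np.testing.assert_allclose(out.variance_fractions[:4], var, atol=1e-10)


class TestMancova:
    def test_single_axis_equals_univariate_sequential_f(self, rng):
        n = 28
        size = rng.normal(size=n)
        groups = ["VCL"] * 14 + ["HL"] * 14
        g = np.array([1.0 if x == "HL" else 0.0 for x in groups])
        y = (0.8 * size + 0.5 * g + rng.normal(size=n))[:, None]
        table = cm.mancova_pillai(y, size, groups).table

        def rss(X):
            b, *_ = np.linalg.lstsq(X, y, rcond=None)
            return float(((y - X @ b) ** 2).sum())

        cols = [np.ones(n), size, g, size * g]
        full = rss(np.column_stack(cols))
        df_e = n - 4
        for i, term in enumerate(("size", "locomotion", "interaction")):
            f_uni = (rss(np.column_stack(cols[: i + 1])) - rss(np.column_stack(cols[: i + 2]))) / (full / df_e)
            assert table.loc[term, "approx_F"] == pytest.approx(f_uni, rel=1e-8)

    def test_null_p_values_roughly_uniform(self, rng):
        ps = []
        for _ in range(150):
            n, q = 25, 3
            size = rng.normal(size=n)
            groups = ["VCL"] * 12 + ["HL"] * 13
            Y = rng.normal(size=(n, q))
            t = cm.mancova_pillai(Y, size, groups).table
            ps.append(t.loc["locomotion", "p"])
        ks = stats.kstest(ps, "uniform").statistic
        assert ks < 0.12

    def test_group_offset_detected_interaction_null(self, rng):
        hits_group = 0
        hits_inter = 0
        reps = 40
        for _ in range(reps):
            n, q = 30, 3
            size = rng.normal(size=n)
            groups = ["VCL"] * 15 + ["HL"] * 15
            g = np.array([1.0 if x == "HL" else 0.0 for x in groups])
            Y = rng.normal(size=(n, q)) + np.outer(g, [2.5, 0, 0])
            t = cm.mancova_pillai(Y, size, groups).table
            hits_group += t.loc["locomotion", "p"] < 0.01
            hits_inter += t.loc["interaction", "p"] < 0.05
        assert hits_group >= 0.9 * reps
        assert hits_inter <= 0.25 * reps

    def test_aliased_term_named(self, rng):
        n = 20
        groups = ["VCL"] * 10 + ["HL"] * 10
        size = np.array([1.0 if x == "HL" else 0.0 for x in groups])  # aliased with group
        Y = rng.normal(size=(n, 2))
        with pytest.raises(ValueError, match="locomotion"):
            cm.mancova_pillai(Y, size, groups)

    def test_too_many_axes_rejected(self, rng):
        Y = rng.normal(size=(10, 8))
        with pytest.raises(ValueError, match="too few"):
            cm.mancova_pillai(Y, rng.normal(size=10), ["a"] * 5 + ["b"] * 5)
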