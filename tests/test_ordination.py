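import numpy as np
import pytest
from scipy.spatial.distance import pdist

import callimorph as cm
from callimorph.ordination import DegenerateGroupsError, ancestral_estimates


class TestPCA:
    def test_rank_one_data_single_axis(self, rng):
        X = np.outer(rng.normal(size=12), rng.normal(size=9))
        res = cm.pca(X)
        assert res.axes.shape[0] == 1
        assert res.variance_fraction[0] == pytest.approx(1.0)

    def test_scores_preserve_pairwise_distances(self, rng):
        X = rng.normal(size=(15, 10))
        res = cm.pca(X)
        d_data = pdist(X - X.mean(0))
        d_scores = pdist(res.scores)
        assert np.abs(d_data - d_scores).max() < 1e-8

    def test_variance_matches_eigendecomposition_oracle(self, rng):
        X = rng.normal(size=(20, 6)) * np.array([3, 2, 1.5, 1, 0.5, 0.1])
        res = cm.pca(X)
        w = np.linalg.eigvalsh(np.cov(X.T, bias=False))[::-1]
        np.testing.assert_allclose(res.variance_fraction, w / w.sum(), atol=1e-10)

    def test_axes_orthonormal_variance_nonincreasing(self, rng):
        res = cm.pca(rng.normal(size=(10, 7)))
        np.testing.assert_allclose(res.axes @ res.axes.T, np.eye(res.axes.shape[0]), atol=1e-10)
        assert (np.diff(res.variance_fraction) <= 1e-12).all()


class TestPhylomorphospace:
    def test_two_tip_root_is_gls_weighted_average(self):
        t = cm.PhyloTree.from_newick("(A:1,B:3);")
        est = ancestral_estimates(t, {"A": np.array([0.0]), "B": np.array([4.0])})
        # GLS weights 1/1 and 1/3 -> root at 1.0
        assert list(est.values())[0][0] == pytest.approx(1.0)

    def test_star_tree_root_is_mean(self, rng):
        from callimorph.trees import star_tree

        st = star_tree(9, 1.0)
        vals = {l: np.array([v]) for l, v in zip(st.tip_labels, rng.normal(size=9))}
        est = ancestral_estimates(st, vals)
        assert list(est.values())[0][0] == pytest.approx(np.mean([v[0] for v in vals.values()]))

    def test_matches_explicit_gls_oracle(self, rng):
        """Internal-node estimates equal the GLS solution computed from the
        full (nodes x tips) covariance by explicit matrix inversion."""
        t = cm.pure_birth_tree(8, seed=5)
        tips = sorted(t.tip_labels)
        y = rng.normal(size=8)
        est = ancestral_estimates(t, {l: np.array([v]) for l, v in zip(tips, y)})
        _, C = t.vcv(order=tips)
        Cinv = np.linalg.inv(C)
        one = np.ones(8)
        root = (one @ Cinv @ y) / (one @ Cinv @ one)
        dt = t.dendropy_tree
        dt.calc_node_root_distances(return_leaf_distances_only=False)
        from callimorph.trees import node_label

        for node in dt.preorder_internal_node_iter():
            under = {l.taxon.label for l in node.leaf_iter()}
            cov = []
            for lab in tips:
                anc = node
                while lab not in {l.taxon.label for l in anc.leaf_iter()}:
                    anc = anc.parent_node
                cov.append(anc.root_distance if lab not in under else node.root_distance)
            expect = root + np.array(cov) @ Cinv @ (y - root)
            assert est[node_label(node)][0] == pytest.approx(expect, abs=1e-9)

    def test_pipeline_integration_has_edges(self, rng):
        t = cm.pure_birth_tree(6, seed=1)
        X = rng.normal(size=(6, 4))
        ords = cm.pca(X, row_ids=sorted(t.tip_labels))
        pm = cm.phylomorphospace(t, ords)
        assert pm.node_scores is not None
        assert len(pm.edges) == 10  # 2n-2 edges on a rooted bifurcating tree


class TestBetweenGroupPCA:
    def test_two_group_axis_is_mean_difference(self, rng):
        X = np.vstack([rng.normal(0, 1, (15, 6)), rng.normal(2, 1, (15, 6))])
        groups = ["a"] * 15 + ["b"] * 15
        res = cm.between_group_pca(X, groups)
        assert res.axes.shape[0] == 1
        md = X[:15].mean(0) - X[15:].mean(0)
        md /= np.linalg.norm(md)
        assert abs(res.axes[0] @ md) >= 1 - 1e-10

    def test_identical_means_degenerate(self, rng):
        X = rng.normal(size=(10, 4))
        X = np.vstack([X, X])
        with pytest.raises(DegenerateGroupsError):
            cm.between_group_pca(X, ["a"] * 10 + ["b"] * 10)

    def test_three_groups_match_eigen_oracle(self, rng):
        offs = np.array([[0, 0, 0, 0.0], [3, 0, 1, 0], [0, 2, 0, 1]])
        X = np.vstack([rng.normal(0, 1, (12, 4)) + offs[i] for i in range(3)])
        groups = sum([[g] * 12 for g in "abc"], [])
        res = cm.between_group_pca(X, groups)
        means = np.vstack([X[i * 12 : (i + 1) * 12].mean(0) for i in range(3)])
        M = means - means.mean(0)
        w, V = np.linalg.eigh(M.T @ M)
        order = np.argsort(w)[::-1]
        for i in range(2):
            assert abs(res.axes[i] @ V[:, order[i]]) == pytest.approx(1.0, abs=1e-8)

    def test_label_swap_antisymmetry(self, rng):
        X = np.vstack([rng.normal(0, 1, (10, 5)), rng.normal(1, 1, (10, 5))])
        g1 = ["a"] * 10 + ["b"] * 10
        g2 = ["b"] * 10 + ["a"] * 10
        r1 = cm.between_group_pca(X, g1)
        r2 = cm.between_group_pca(X, g2)
        # deterministic sign convention makes the axes equal up to sign
        assert abs(r1.axes[0] @ r2.axes[0]) == pytest.approx(1.0, abs=1e-10)


class TestClassifyTypicality:
    def test_well_separated_clouds_perfect(self, rng):
        X = np.vstack([rng.normal(0, 1, (18, 3)), rng.normal(10, 1, (18, 3))])
        rep = cm.classify_typicality(X, ["a"] * 18 + ["b"] * 18, cross_validate=True)
        assert rep.accuracy == 100.0

    def test_specimen_at_group_mean_has_max_typicality(self, rng):
        # group a: zero-sum offsets around m, specimen 0 exactly at m
        m = np.array([2.0, -1.0])
        offsets = rng.normal(size=(9, 2))
        offsets -= offsets.mean(0)
        Xa = np.vstack([m, m + offsets])
        Xb = rng.normal(8, 1, (10, 2))
        X = np.vstack([Xa, Xb])
        groups = ["a"] * 10 + ["b"] * 10
        rep = cm.classify_typicality(X, groups, cross_validate=False)
        typ_a = rep.specimens["typicality_a"].to_numpy()
        assert typ_a[0] == typ_a.max()
        assert typ_a[0] == pytest.approx(1.0)  # zero Mahalanobis distance

    def test_chance_level_under_shuffled_labels(self, rng):
        groups = ["a"] * 20 + ["b"] * 20
        accs = [
            cm.classify_typicality(rng.normal(size=(40, 3)), groups, cross_validate=True).accuracy
            for _ in range(30)
        ]
        assert 35 < np.mean(accs) < 65

    def test_cv_not_better_than_resubstitution(self, rng):
        diffs = []
        for _ in range(40):
            X = np.vstack([rng.normal(0, 1, (12, 3)), rng.normal(0.8, 1, (12, 3))])
            groups = ["a"] * 12 + ["b"] * 12
            cv = cm.classify_typicality(X, groups, cross_validate=True).accuracy
            rs = cm.classify_typicality(X, groups, cross_validate=False).accuracy
            diffs.append(rs - cv)
        assert np.mean(diffs) >= 0

    def test_bgpca_cv_avoids_projection_leak(self, rng):
        """Cross-validated bgPCA classification is chance-level on random
        labels; keeping the axes fixed during CV would be above chance."""
        groups = ["a"] * 15 + ["b"] * 15
        cv_acc, leaky_acc = [], []
        for _ in range(25):
            X = rng.normal(size=(30, 5))
            cv_acc.append(cm.bgpca_classify(X, groups, cross_validate=True).accuracy)
            bg = cm.between_group_pca(X, groups)
            leaky_acc.append(cm.classify_typicality(bg.scores, groups, cross_validate=True).accuracy)
        assert 38 <= np.mean(cv_acc) <= 62
        assert np.mean(leaky_acc) > np.mean(cv_acc)

    def test_report_json_round_trip(self, tmp_path, rng):
        from callimorph.ordination import ClassificationReport

        X = np.vstack([rng.normal(0, 1, (10, 2)), rng.normal(5, 1, (10, 2))])
        rep = cm.classify_typicality(X, ["a"] * 10 + ["b"] * 10)
        p = tmp_path / "cls.json"
        rep.to_json(p)
        back = ClassificationReport.from_json(p)
        assert back.accuracy == rep.accuracy
        assert back.specimens["assigned"].tolist() == rep.specimens["assigned"].tolist()

    def test_dimensionality_guard(self, rng):
        X = rng.normal(size=(8, 5))
        with pytest.raises(ValueError, match="dimension"):
            cm.classify_typicality(X, ["a"] * 4 + ["b"] * 4)


class TestPermutationDistance:
    def test_duplicated_data_p_near_one(self, rng):
        X = rng.normal(size=(10, 4))
        X = np.vstack([X, X])
        res = cm.permutation_group_distance(X, ["a"] * 10 + ["b"] * 10, n_perm=200, seed=0)
        assert res.observed == pytest.approx(0.0, abs=1e-12)
        assert res.p_value > 0.95

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(20, 3))
        g = ["a"] * 10 + ["b"] * 10
        a = cm.permutation_group_distance(X, g, n_perm=500, seed=9)
        b = cm.permutation_group_distance(X, g, n_perm=500, seed=9)
        assert a.p_value == b.p_value and a.observed == b.observed

    def test_separation_detected(self, rng):
        X = np.vstack([rng.normal(0, 1, (12, 4)), rng.normal(4, 1, (12, 4))])
        res = cm.permutation_group_distance(X, ["a"] * 12 + ["b"] * 12, n_perm=500, seed=1)
        assert res.p_value < 0.01


class TestAxisEndpointShapes:
    def test_zero_score_gives_consensus(self, rng):
        X = rng.normal(size=(10, 12))
        res = cm.pca(X)
        lo, hi = cm.axis_endpoint_shapes(res, axis=0, quantiles=(0.5, 0.5))
        med = float(np.quantile(res.scores[:, 0], 0.5))
        expect = (res.mean + med * res.axes[0]).reshape(-1, 3)
        np.testing.assert_allclose(lo, expect, atol=1e-12)

    def test_full_axis_reconstruction_recovers_specimen(self, rng):
        X = rng.normal(size=(8, 9))
        res = cm.pca(X)
        i = 3
        recon = res.mean + res.scores[i] @ res.axes
        np.testing.assert_allclose(recon, X[i], atol=1e-8)

    def test_endpoints_differ_along_axis_only(self, rng):
        X = rng.normal(size=(14, 15))
        res = cm.pca(X)
        lo, hi = cm.axis_endpoint_shapes(res, axis=1)
        diff = (hi - lo).ravel()
        v = res.axes[1]
        residual = diff - (diff @ v) * v
        assert np.linalg.norm(residual) < 1e-8

    def test_invalid_axis_rejected(self, rng):
        res = cm.pca(rng.normal(size=(5, 6)))
        with pytest.raises(ValueError):
            cm.axis_endpoint_shapes(res, axis=99)
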