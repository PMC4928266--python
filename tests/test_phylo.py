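"""Phylogenetic comparative methods: covariance, signal, PGLS, ancestors.

Reference values for the 4-taxon fixture were computed with the independent
R implementations (ape/phytools for K, λ and ancestral states; nlme::gls with
a Brownian correlation for PGLS) and frozen here.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from paridmorph import data_io, phylo
from paridmorph.synthetic_data import simulate_bm_traits, simulate_tree

FIXTURE_NEWICK = "((A:0.3,B:0.3):0.7,(C:0.6,D:0.6):0.4);"
FIXTURE_X = {"A": 1.2, "B": 0.9, "C": 2.5, "D": 2.1}
FIXTURE_Y = {"A": 2.0, "B": 1.6, "C": 4.9, "D": 4.6}


@pytest.fixture(scope="module")
def fixture_tree():
    return data_io.read_newick(FIXTURE_NEWICK)


class TestPhyloVcv:
    def test_cherry(self):
        _, C = phylo.phylo_vcv(data_io.read_newick("(A:1,B:1);"))
        assert np.allclose(C, np.eye(2))

    def test_three_taxon(self):
        t = data_io.read_newick("((A:1,B:1):0.5,C:1.5);")
        labels, C = phylo.phylo_vcv(t)
        i = {lab: k for k, lab in enumerate(labels)}
        assert C[i["A"], i["B"]] == pytest.approx(0.5)
        assert C[i["A"], i["C"]] == pytest.approx(0.0)
        assert np.allclose(np.diag(C), 1.5)

    def test_positive_semidefinite_sweep(self):
        for seed in range(200):
            t = simulate_tree(int(3 + seed % 8), seed=seed)
            _, C = phylo.phylo_vcv(t)
            assert np.allclose(C, C.T)
            assert np.linalg.eigvalsh(C).min() > -1e-10


class TestBlombergK:
    def test_matches_reference_implementation(self, fixture_tree):
        res = phylo.blomberg_k(fixture_tree, FIXTURE_X, n_perm=99, seed=0)
        assert res.estimate == pytest.approx(1.604438, abs=1e-5)

    def test_p_respects_plus_one_bound(self, fixture_tree):
        res = phylo.blomberg_k(fixture_tree, FIXTURE_X, n_perm=999, seed=0)
        assert 1.0 / 1000 <= res.p <= 1.0

    def test_affine_invariance(self):
        t = simulate_tree(12, seed=3)
        x = simulate_bm_traits(t, 0.0, 1.0, seed=4)
        k1 = phylo.blomberg_k(t, x, n_perm=99, seed=5).estimate
        k2 = phylo.blomberg_k(
            t, {k: 3.0 * v - 7.0 for k, v in x.items()}, n_perm=99, seed=5
        ).estimate
        assert k1 == pytest.approx(k2, rel=1e-9)

    def test_constant_trait_errors(self, fixture_tree):
        with pytest.raises(ValueError):
            phylo.blomberg_k(fixture_tree, {k: 1.0 for k in FIXTURE_X}, seed=0)

    def test_missing_tip_errors(self, fixture_tree):
        with pytest.raises(ValueError, match="missing"):
            phylo.blomberg_k(fixture_tree, {"A": 1.0, "B": 2.0}, seed=0)


class TestPagelLambda:
    def test_matches_reference_implementation(self, fixture_tree):
        res = phylo.pagel_lambda(fixture_tree, FIXTURE_X)
        assert res.estimate == pytest.approx(1.271498, abs=1e-4)
        assert res.logL == pytest.approx(-2.767590, abs=1e-4)

    def test_lambda_zero_likelihood_is_iid_normal(self, fixture_tree):
        """At λ=0 the model collapses to independent normals with variances
        proportional to the tip depths."""
        labels, C = fixture_tree.vcv()
        x = np.array([FIXTURE_X[l] for l in labels])
        n = len(x)
        d = np.diag(C)
        w = 1.0 / d
        mu = (w * x).sum() / w.sum()
        s2 = ((x - mu) ** 2 / d).sum() / n
        expected = stats.norm.logpdf(x, mu, np.sqrt(s2 * d)).sum()
        assert phylo._lambda_loglik(x, C, 0.0) == pytest.approx(expected, abs=1e-9)

    def test_optimum_beats_endpoints(self):
        t = simulate_tree(16, seed=9)
        x = simulate_bm_traits(t, 0.0, 1.0, seed=10)
        res = phylo.pagel_lambda(t, x)
        xv, _, C = phylo._align_trait(t, x)
        assert res.logL >= phylo._lambda_loglik(xv, C, 0.0) - 1e-9
        assert res.logL >= phylo._lambda_loglik(xv, C, 1.0) - 1e-9

    def test_affine_invariance(self):
        t = simulate_tree(12, seed=3)
        x = simulate_bm_traits(t, 0.0, 1.0, seed=4)
        l1 = phylo.pagel_lambda(t, x).estimate
        l2 = phylo.pagel_lambda(t, {k: -2.0 * v + 5.0 for k, v in x.items()}).estimate
        assert l1 == pytest.approx(l2, abs=1e-6)


class TestPgls:
    def test_matches_reference_implementation(self, fixture_tree):
        res = phylo.pgls(FIXTURE_Y, FIXTURE_X, fixture_tree)
        assert res.slope == pytest.approx(2.0745212, abs=1e-6)
        assert res.intercept == pytest.approx(-0.1825562, abs=1e-6)
        assert res.slope_se == pytest.approx(0.3927848, abs=1e-6)
        assert res.t == pytest.approx(5.2815718, abs=1e-5)
        assert res.p == pytest.approx(0.0340294, abs=1e-6)

    def test_star_tree_equals_ols(self):
        star = data_io.read_newick("(A:1,B:1,C:1,D:1,E:1);")
        rng = np.random.default_rng(0)
        x = dict(zip("ABCDE", rng.normal(size=5)))
        y = dict(zip("ABCDE", rng.normal(size=5)))
        res = phylo.pgls(y, x, star)
        xv = np.array([x[k] for k in "ABCDE"])
        yv = np.array([y[k] for k in "ABCDE"])
        ref = stats.linregress(xv, yv)
        assert res.slope == pytest.approx(ref.slope, abs=1e-9)
        assert res.intercept == pytest.approx(ref.intercept, abs=1e-9)

    def test_branch_length_scale_invariance(self, fixture_tree):
        doubled = data_io.read_newick("((A:0.6,B:0.6):1.4,(C:1.2,D:1.2):0.8);")
        r1 = phylo.pgls(FIXTURE_Y, FIXTURE_X, fixture_tree)
        r2 = phylo.pgls(FIXTURE_Y, FIXTURE_X, doubled)
        assert r1.slope == pytest.approx(r2.slope, rel=1e-9)
        assert r1.t == pytest.approx(r2.t, rel=1e-9)

    def test_slope_recovery_under_bm(self):
        """Mean estimated slope over replicates is within 2 Monte-Carlo
        standard errors of the generating slope."""
        t = simulate_tree(16, seed=20)
        beta = 1.5
        rng = np.random.default_rng(21)
        slopes = []
        for _ in range(500):
            x = simulate_bm_traits(t, 0.0, 1.0, seed=rng)
            eps = simulate_bm_traits(t, 0.0, 0.5, seed=rng)
            y = {k: beta * x[k] + eps[k] for k in x}
            slopes.append(phylo.pgls(y, x, t).slope)
        slopes = np.asarray(slopes)
        se = slopes.std(ddof=1) / np.sqrt(len(slopes))
        assert abs(slopes.mean() - beta) < 2 * se + 1e-12


class TestSquaredChangeParsimony:
    def test_equal_cherry(self):
        t = data_io.read_newick("(A:1,B:1);")
        anc = phylo.squared_change_parsimony(t, {"A": 0.0, "B": 4.0})
        assert list(anc.node_values.values())[0] == pytest.approx(2.0)

    def test_weighted_cherry(self):
        """Weights 1/branch: root = (0/1 + 4/3) / (1 + 1/3) = 1."""
        t = data_io.read_newick("(A:1,B:3);")
        anc = phylo.squared_change_parsimony(t, {"A": 0.0, "B": 4.0})
        assert list(anc.node_values.values())[0] == pytest.approx(1.0)

    def test_matches_reference_implementation(self, fixture_tree):
        anc = phylo.squared_change_parsimony(fixture_tree, FIXTURE_X)
        vals = sorted(anc.node_values.values())
        assert vals == pytest.approx(
            sorted([1.735484, 1.170968, 2.058065]), abs=1e-5
        )

    def test_matches_numerical_minimizer(self):
        """Exact linear solve equals a generic optimizer of the weighted sum
        of squared changes, across random trees."""
        for seed in range(100):
            t = simulate_tree(int(4 + seed % 5), seed=seed)
            rng = np.random.default_rng(seed)
            tips = dict(simulate_bm_traits(t, 0.0, 1.0, seed=rng))
            anc = phylo.squared_change_parsimony(t, tips)
            ids = phylo._node_ids(t)
            internals = [n for n in t.dendropy_tree.preorder_node_iter() if not n.is_leaf()]

            pos = {ids[n]: i for i, n in enumerate(internals)}

            def objective(v):
                total = 0.0
                grad = np.zeros_like(v)
                for node in t.dendropy_tree.preorder_node_iter():
                    if node.parent_node is None:
                        continue
                    pi = pos[ids[node.parent_node]]
                    if node.is_leaf():
                        nv, ni = tips[node.taxon.label], None
                    else:
                        ni = pos[ids[node]]
                        nv = v[ni]
                    diff = (nv - v[pi]) / node.edge.length
                    total += (nv - v[pi]) * diff
                    grad[pi] -= 2 * diff
                    if ni is not None:
                        grad[ni] += 2 * diff
                return total, grad

            x0 = np.full(len(internals), np.mean(list(tips.values())))
            opt = optimize.minimize(
                objective, x0, jac=True, method="BFGS", options={"gtol": 1e-12}
            )
            mine = np.array([anc.node_values[ids[n]] for n in internals])
            assert np.abs(mine - opt.x).max() < 1e-6

    def test_root_equals_gls_mean(self):
        """The reconstruction at the root equals the phylogenetic GLS mean."""
        t = simulate_tree(10, seed=7)
        x = simulate_bm_traits(t, 1.0, 0.8, seed=8)
        anc = phylo.squared_change_parsimony(t, x)
        labels, C = t.vcv()
        xv = np.array([x[l] for l in labels])
        ones = np.ones(len(xv))
        Ci = np.linalg.inv(C)
        gls_mean = ones @ Ci @ xv / (ones @ Ci @ ones)
        root_id = phylo._node_ids(t)[t.dendropy_tree.seed_node]
        assert anc.node_values[root_id] == pytest.approx(gls_mean, abs=1e-9)

    def test_values_inside_tip_range(self):
        t = simulate_tree(12, seed=2)
        x = simulate_bm_traits(t, 0.0, 1.0, seed=3)
        anc = phylo.squared_change_parsimony(t, x)
        lo, hi = min(x.values()), max(x.values())
        assert all(lo - 1e-12 <= v <= hi + 1e-12 for v in anc.node_values.values())

    def test_zero_length_internal_branch_merges_nodes(self):
        t = data_io.read_newick("((A:1,B:1):0,C:1);")
        anc = phylo.squared_change_parsimony(t, {"A": 0.0, "B": 3.0, "C": 3.0})
        vals = list(anc.node_values.values())
        assert vals[0] == pytest.approx(vals[1])


class TestPhylomorphospace:
    def test_tips_keep_their_scores_and_edges_count(self):
        t = simulate_tree(9, seed=5)
        rng = np.random.default_rng(6)
        scores = pd.DataFrame(
            rng.normal(size=(9, 2)), index=t.tip_labels, columns=["PC1", "PC2"]
        )
        nodes, edges = phylo.phylomorphospace(t, scores)
        tips = nodes[nodes["kind"] == "tip"].set_index("node_id")
        for lab in t.tip_labels:
            assert tips.loc[lab, "PC1"] == scores.loc[lab, "PC1"]
        assert len(edges) == 2 * 9 - 2  # binary tree edge count
        # internal nodes stay inside the bounding box of the tips, per axis
        inner = nodes[nodes["kind"] == "internal"]
        for ax in ("PC1", "PC2"):
            assert inner[ax].between(scores[ax].min(), scores[ax].max()).all()

    def test_missing_tip_score_errors(self):
        t = simulate_tree(4, seed=1)
        scores = pd.DataFrame(
            np.zeros((3, 2)), index=t.tip_labels[:3], columns=["PC1", "PC2"]
        )
        with pytest.raises(ValueError, match="missing"):
            phylo.phylomorphospace(t, scores)
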