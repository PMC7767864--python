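import numpy as np
import pytest
from scipy import stats

from floricolor.phylo import (
    NewickParseError,
    Phylogeny,
    ancestral_states_bm,
    brownian_rate_ml,
    holm_adjust,
    phyl_anova,
    read_newick,
    simulate_brownian,
)
from floricolor.synthetic_data import make_tree


class TestReadNewick:
    def test_two_tip_tree_identity_covariance(self):
        t = read_newick("(A:1,B:1):0;")
        assert t.n_tips == 2
        np.testing.assert_allclose(t.vcv(), np.eye(2))

    def test_shared_path_off_diagonal(self):
        t = read_newick("((A:1,B:1):1,C:2):0;")
        c = t.vcv()
        idx = {label: i for i, label in enumerate(t.tip_labels)}
        assert c[idx["A"], idx["B"]] == pytest.approx(1.0)
        assert c[idx["A"], idx["C"]] == pytest.approx(0.0)
        assert c[idx["A"], idx["A"]] == pytest.approx(2.0)

    def test_malformed_rejected(self):
        with pytest.raises(NewickParseError):
            read_newick("(A:1,B:1")
        with pytest.raises(NewickParseError, match="branch length"):
            read_newick("(A:1,B);")

    def test_duplicate_tips_rejected(self):
        with pytest.raises(NewickParseError, match="duplicate"):
            read_newick("(A:1,A:1):0;")

    def test_pruning_preserves_pairwise_path_lengths(self):
        t = make_tree(40, seed=3)
        keep = t.tip_labels[:25]
        sub = t.prune_to(keep)
        c_full = t.vcv()
        c_sub = sub.vcv()
        i_full = {label: i for i, label in enumerate(t.tip_labels)}
        i_sub = {label: i for i, label in enumerate(sub.tip_labels)}
        # patristic distance d(i,j) = C_ii + C_jj - 2 C_ij must be preserved
        for a in keep[:10]:
            for b in keep[10:20]:
                d_full = (
                    c_full[i_full[a], i_full[a]]
                    + c_full[i_full[b], i_full[b]]
                    - 2 * c_full[i_full[a], i_full[b]]
                )
                d_sub = (
                    c_sub[i_sub[a], i_sub[a]]
                    + c_sub[i_sub[b], i_sub[b]]
                    - 2 * c_sub[i_sub[a], i_sub[b]]
                )
                assert d_sub == pytest.approx(d_full, abs=1e-9)


class TestSimulateBrownian:
    def test_two_tip_contrast_variance(self):
        t = read_newick("(A:1,B:1):0;")
        sims = simulate_brownian(t, sigma2=2.0, seed=0, n_draws=10_000)
        contrast_var = np.var(sims[:, 0] - sims[:, 1], ddof=1)
        assert contrast_var == pytest.approx(2 * 2.0, rel=0.05)

    def test_mean_is_root_value(self):
        t = read_newick("(A:1,B:1):0;")
        sims = simulate_brownian(t, sigma2=1.0, root_value=7.0, seed=1, n_draws=10_000)
        assert sims.mean() == pytest.approx(7.0, abs=0.05)

    def test_degenerate_star_collapses_to_root(self):
        t = read_newick("(A:0,B:0,C:0):0;")
        sims = simulate_brownian(t, sigma2=1.0, root_value=3.0, seed=2, n_draws=5)
        np.testing.assert_allclose(sims, 3.0, atol=1e-7)

    def test_invalid_rate_rejected(self):
        t = read_newick("(A:1,B:1):0;")
        with pytest.raises(ValueError):
            simulate_brownian(t, sigma2=0.0)

    def test_covariance_matches_tree_structure(self):
        t = read_newick("((A:1,B:1):2,C:3):0;")
        sims = simulate_brownian(t, sigma2=1.0, seed=3, n_draws=40_000)
        emp = np.cov(sims.T)
        np.testing.assert_allclose(emp, t.vcv(), atol=0.08)


class TestPhylAnova:
    def test_f_matches_textbook_oracle(self):
        t = make_tree(20, seed=5)
        rng = np.random.default_rng(5)
        trait = simulate_brownian(t, 1.0, seed=6)[0]
        groups = rng.choice(["x", "y", "z"], size=20)
        while min(np.sum(groups == g) for g in "xyz") < 2:
            groups = rng.choice(["x", "y", "z"], size=20)
        res = phyl_anova(t, trait, groups, n_sim=99, seed=1)
        expected_f = stats.f_oneway(*(trait[groups == g] for g in "xyz")).statistic
        assert res.f_obs == pytest.approx(expected_f, abs=1e-10)

    def test_constant_within_groups_gives_minimal_p(self):
        t = make_tree(10, seed=8)
        groups = np.array(["a"] * 5 + ["b"] * 5)
        trait = np.where(groups == "a", 1.0, 5.0)
        res = phyl_anova(t, trait, groups, n_sim=199, seed=2)
        assert res.p_sim == pytest.approx(1 / 200)

    def test_seed_reproducible(self):
        t = make_tree(12, seed=9)
        trait = simulate_brownian(t, 1.0, seed=10)[0]
        groups = np.array(["a", "b"] * 6)
        r1 = phyl_anova(t, trait, groups, n_sim=199, seed=3)
        r2 = phyl_anova(t, trait, groups, n_sim=199, seed=3)
        assert r1.p_sim == r2.p_sim

    def test_singleton_group_rejected(self):
        t = make_tree(4, seed=11)
        with pytest.raises(ValueError):
            phyl_anova(t, np.arange(4.0), ["a", "a", "a", "b"], n_sim=9)

    @pytest.mark.parametrize(
        "newick",
        [
            None,  # pure-birth tree
            "(" + ",".join(f"t{i}:1" for i in range(16)) + "):0;",  # star
            None,
        ],
    )
    def test_type_I_error_calibrated(self, newick):
        """Random groups + BM trait: rejection rate near the nominal 5%."""
        t = read_newick(newick) if newick else make_tree(16, seed=13)
        rng = np.random.default_rng(99)
        groups = np.array(["a", "b"] * 8)
        hits = 0
        n_rep = 60
        for _ in range(n_rep):
            trait = simulate_brownian(t, 1.0, rng=rng)[0]
            res = phyl_anova(t, trait, groups, n_sim=99, seed=int(rng.integers(2**31)))
            hits += res.p_sim <= 0.05
        assert hits / n_rep < 0.17  # loose 3x bound for a quick check


class TestHolm:
    def test_single_p_unchanged(self):
        assert holm_adjust([0.03]) == [pytest.approx(0.03)]

    def test_two_p_stepdown(self):
        adj = holm_adjust([0.01, 0.04])
        assert adj[0] == pytest.approx(0.02)
        assert adj[1] == pytest.approx(0.04)

    def test_dominance_property(self):
        rng = np.random.default_rng(14)
        raw = rng.uniform(0.001, 1.0, size=10)
        adj = holm_adjust(raw)
        assert all(a >= r - 1e-15 for a, r in zip(adj, raw))
        assert all(a <= 1.0 for a in adj)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.0, 0.5])


def conditional_gls_oracle(t: Phylogeny, y: np.ndarray) -> np.ndarray:
    """Independent ancestral-state oracle via explicit covariance inversion.

    Builds the full tip+node shared-path covariance and returns
    a + C_nt C_tt^-1 (y - a) with a the GLS phylogenetic mean.
    """
    depth = {}
    for node in t.tree.preorder_node_iter():
        parent = node.parent_node
        depth[id(node)] = (depth[id(parent)] if parent else 0.0) + (node.edge.length or 0.0)

    def mrca_depth(n1, n2):
        anc1 = set()
        n = n1
        while n is not None:
            anc1.add(id(n))
            n = n.parent_node
        n = n2
        while id(n) not in anc1:
            n = n.parent_node
        return depth[id(n)]

    tips = [n for n in t.tree.leaf_node_iter()]
    tip_order = {n.taxon.label: n for n in tips}
    tips = [tip_order[label] for label in t.tip_labels]
    internal = [n for n in t.tree.preorder_node_iter() if not n.is_leaf()]
    c_tt = np.array([[mrca_depth(a, b) for b in tips] for a in tips])
    c_nt = np.array([[mrca_depth(a, b) for b in tips] for a in internal])
    cinv = np.linalg.inv(c_tt)
    ones = np.ones(len(tips))
    a = (ones @ cinv @ y) / (ones @ cinv @ ones)
    return a + c_nt @ cinv @ (y - a)


class TestAncestralStates:
    def test_two_tips_equal_lengths_root_is_mean(self):
        t = read_newick("(A:1,B:1):0;")
        est = ancestral_states_bm(t, np.array([2.0, 8.0]))
        assert est.root_estimate == pytest.approx(5.0)

    def test_star_tree_root_is_arithmetic_mean(self):
        t = read_newick("(A:1,B:1,C:1,D:1):0;")
        vals = np.array([1.0, 2.0, 3.0, 10.0])
        est = ancestral_states_bm(t, vals)
        assert est.root_estimate == pytest.approx(vals.mean())

    def test_matches_explicit_gls_oracle_on_random_trees(self):
        for seed in (21, 22, 23):
            t = make_tree(10, seed=seed)
            rng = np.random.default_rng(seed)
            y = rng.uniform(0, 100, 10)
            est = ancestral_states_bm(t, y)
            oracle = conditional_gls_oracle(t, y)
            np.testing.assert_allclose(est.estimates, oracle, atol=1e-8)

    def test_root_equals_gls_phylogenetic_mean(self):
        t = make_tree(12, seed=30)
        rng = np.random.default_rng(30)
        y = rng.normal(size=12)
        est = ancestral_states_bm(t, y)
        _, gls_mean = brownian_rate_ml(t, y)
        assert est.root_estimate == pytest.approx(gls_mean, abs=1e-10)

    def test_estimates_within_tip_range(self):
        t = make_tree(15, seed=31)
        rng = np.random.default_rng(31)
        y = rng.uniform(0, 100, 15)
        est = ancestral_states_bm(t, y)
        assert est.estimates.min() >= y.min() - 1e-9
        assert est.estimates.max() <= y.max() + 1e-9

    def test_invariant_to_tip_order_and_dict_input(self):
        t = make_tree(8, seed=32)
        rng = np.random.default_rng(32)
        y = rng.normal(size=8)
        by_label = dict(zip(t.tip_labels, y))
        est_arr = ancestral_states_bm(t, y)
        est_dict = ancestral_states_bm(t, by_label)
        np.testing.assert_allclose(est_arr.estimates, est_dict.estimates, atol=1e-12)

    def test_zero_length_edge_triggers_ridge_warning(self):
        t = read_newick("((A:0,B:1):1,C:2):0;")
        with pytest.warns(UserWarning, match="ridge"):
            ancestral_states_bm(t, np.array([1.0, 2.0, 3.0]))
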