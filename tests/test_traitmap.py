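"""Mk likelihood (against exhaustive enumeration), ML fitting, the ER/ARD
likelihood-ratio test, and stochastic mapping."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from genbias.traitmap import (
    MISSING,
    MkModel,
    Phylogeny,
    aggregate,
    expected_endpoint_changes_exact,
    fit_and_map_genes,
    fit_mk,
    fit_mk_pooled,
    lrt_er_ard,
    mk_loglik,
    simmap,
)

TREE4 = "((A:0.6,B:0.6):0.8,(C:0.7,D:0.5):0.9);"


def enumeration_loglik(tree: Phylogeny, tips: dict[str, int], model: MkModel) -> float:
    """Oracle: sum the joint probability over every assignment of states to
    internal nodes AND missing tips."""
    fixed = {
        tree.leaf_index[l]: s for l, s in tips.items() if s != MISSING
    }
    free = [i for i in tree.postorder if i not in fixed]
    total = 0.0
    for assign in itertools.product([0, 1], repeat=len(free)):
        st = dict(fixed)
        st.update(dict(zip(free, assign)))
        p = model.root_prior[st[tree.root]]
        for child, parent in tree.parent.items():
            p *= model.transition_matrix(tree.blen[child])[st[parent], st[child]]
        total += p
    return math.log(total)


def random_tree(rng, n_leaves: int) -> str:
    """Random rooted binary tree over n_leaves labelled tips."""
    nodes = [f"L{i}:{rng.uniform(0.05, 1.5):.4f}" for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):{rng.uniform(0.05, 1.5):.4f}")
    newick = nodes[0]
    return newick[: newick.rfind(":")] + ";"


class TestMkLoglik:
    def test_matches_enumeration_on_random_trees(self):
        """Pruning equals exhaustive enumeration on trees with 3-5 leaves
        (random rates, random states, occasional missing tip)."""
        rng = np.random.default_rng(2024)
        for trial in range(100):
            n = int(rng.integers(3, 6))
            tree = Phylogeny.from_newick(random_tree(rng, n))
            model = MkModel(
                float(rng.uniform(0.01, 3.0)), float(rng.uniform(0.01, 3.0))
            )
            tips = {l: int(rng.integers(0, 2)) for l in tree.leaves}
            if rng.random() < 0.3:
                tips[tree.leaves[0]] = MISSING
            assert mk_loglik(tree, tips, model) == pytest.approx(
                enumeration_loglik(tree, tips, model), abs=1e-10
            )

    def test_two_leaf_no_change_limit(self):
        tree = Phylogeny.from_newick("(A:1e-9,B:1e-9);")
        lik = math.exp(mk_loglik(tree, {"A": 0, "B": 0}, MkModel(1.0, 1.0)))
        assert lik == pytest.approx(0.5, abs=1e-6)

    def test_two_leaf_saturated_limit(self):
        tree = Phylogeny.from_newick("(A:1e4,B:1e4);")
        lik = math.exp(mk_loglik(tree, {"A": 0, "B": 0}, MkModel(1.0, 1.0)))
        assert lik == pytest.approx(0.25, abs=1e-6)

    def test_unknown_leaf_errors(self):
        tree = Phylogeny.from_newick(TREE4)
        with pytest.raises(ValueError, match="unknown"):
            mk_loglik(tree, {"Z": 1}, MkModel(1, 1))

    def test_invariant_under_child_reordering(self):
        a = Phylogeny.from_newick("((A:0.6,B:0.6):0.8,(C:0.7,D:0.5):0.9);")
        b = Phylogeny.from_newick("((D:0.5,C:0.7):0.9,(B:0.6,A:0.6):0.8);")
        m = MkModel(0.4, 1.1)
        tips = {"A": 1, "B": 0, "C": 0, "D": 1}
        assert mk_loglik(a, tips, m) == pytest.approx(mk_loglik(b, tips, m), abs=1e-12)


class TestFitMk:
    def test_invariant_pattern_pins_rate_at_lower_bound(self):
        tree = Phylogeny.from_newick(TREE4)
        fit = fit_mk(tree, {l: 0 for l in tree.leaves}, "ER")
        assert fit.invariant
        assert fit.model.q01 == pytest.approx(1e-8)
        assert fit.lnL == pytest.approx(math.log(0.5), abs=1e-6)

    def test_ard_never_below_er(self):
        rng = np.random.default_rng(5)
        tree = Phylogeny.from_newick(TREE4)
        for _ in range(10):
            tips = {l: int(rng.integers(0, 2)) for l in tree.leaves}
            if len(set(tips.values())) == 1:
                continue
            er = fit_mk(tree, tips, "ER")
            ard = fit_mk(tree, tips, "ARD")
            assert ard.lnL >= er.lnL - 1e-6

    def test_all_missing_rejected(self):
        tree = Phylogeny.from_newick(TREE4)
        with pytest.raises(ValueError):
            fit_mk(tree, {l: MISSING for l in tree.leaves}, "ER")

    def test_pooled_recovery_under_er(self):
        """500 genes simulated under ER q = 1: the pooled estimate lands
        within 15% of the truth."""
        from genbias.syndata import simulate_trait_history

        tree = Phylogeny.from_newick(TREE4)
        rng = np.random.default_rng(17)
        genes = []
        for _ in range(500):
            h = simulate_trait_history(tree, 1.0, 1.0, 0.5, rng)
            genes.append({l: h[i] for l, i in tree.leaf_index.items()})
        fit = fit_mk_pooled(tree, genes, "ER")
        assert 0.85 <= fit.model.q01 <= 1.15


class TestLrt:
    def test_equal_likelihoods_p_one(self):
        assert lrt_er_ard(-10.0, -10.0) == pytest.approx(1.0)

    def test_critical_value(self):
        assert lrt_er_ard(0.0, 3.841 / 2) == pytest.approx(0.05, abs=1e-3)

    def test_negative_statistic_clamped(self):
        assert lrt_er_ard(-9.0, -9.5) == pytest.approx(1.0)


class TestSimmap:
    def test_zero_rates_consistent_tips_no_events(self):
        tree = Phylogeny.from_newick(TREE4)
        model = MkModel(0.0, 0.0)
        res = simmap(tree, {l: 0 for l in tree.leaves}, model, n_maps=50, seed=1)
        assert all(v == 0 for v in res.branch_expected_gains.values())
        assert all(v == 0 for v in res.branch_expected_losses.values())

    def test_two_node_fixed_endpoints(self):
        """Root constrained to 0 (prior), tip observed 1: every map records
        exactly one gain on that branch."""
        tree = Phylogeny.from_newick("(A:1.0,B:1.0);")
        model = MkModel(1.0, 1.0, root_prior=(1.0, 0.0))
        res = simmap(tree, {"A": 1, "B": 0}, model, n_maps=200, seed=2)
        assert res.branch_expected_gains["A"] == pytest.approx(1.0)
        assert res.branch_expected_losses["A"] == 0.0

    def test_matches_exact_endpoint_posterior(self):
        """MC event expectations converge to the inside-outside joint
        parent/child posterior within 3 MC standard errors."""
        tree = Phylogeny.from_newick(TREE4)
        model = MkModel(0.8, 1.4)
        tips = {"A": 1, "B": 0, "C": 1, "D": MISSING}
        n_maps = 20000
        exact = expected_endpoint_changes_exact(tree, tips, model)
        res = simmap(tree, tips, model, n_maps=n_maps, seed=3)
        for b, probs in exact.items():
            for kind, got in (
                ("gain", res.branch_expected_gains[b]),
                ("loss", res.branch_expected_losses[b]),
            ):
                p = probs[kind]
                se = math.sqrt(max(p * (1 - p), 1e-12) / n_maps)
                assert abs(got - p) <= 3 * se + 1e-9, (b, kind)

    def test_root_child_gains_bounded_by_root_posterior(self):
        """Gains on a root-child branch require root state 0, so their MC
        frequency cannot exceed the analytic root-0 posterior mass."""
        tree = Phylogeny.from_newick(TREE4)
        model = MkModel(0.6, 0.9)
        tips = {"A": 1, "B": 1, "C": 0, "D": 0}
        from genbias.traitmap import _partials

        L = _partials(tree, tips, model)
        w = np.array(model.root_prior) * L[tree.root]
        p0 = w[0] / w.sum()
        n = 20000
        res = simmap(tree, tips, model, n_maps=n, seed=7)
        se = math.sqrt(0.25 / n)
        for b in ("A|B", "C|D"):
            assert res.branch_expected_gains[b] <= p0 + 3 * se

    def test_zero_likelihood_configuration_errors(self):
        tree = Phylogeny.from_newick(TREE4)
        with pytest.raises(ValueError, match="zero likelihood"):
            simmap(tree, {"A": 1, "B": 0, "C": 0, "D": 0}, MkModel(0.0, 0.0), n_maps=10, seed=1)


class TestAggregate:
    def test_two_identical_genes_double_totals(self):
        tree = Phylogeny.from_newick(TREE4)
        model = MkModel(0.8, 0.8)
        tips = {"A": 1, "B": 0, "C": 0, "D": 0}
        res = simmap(tree, tips, model, n_maps=500, seed=11)
        agg = aggregate({"g1": res, "g2": res}, tree)
        for b in tree.branch_ids:
            assert agg["branch_totals"][b]["gain"] == pytest.approx(
                2 * res.branch_expected_gains[b]
            )

    def test_empty_input_marked_empty(self):
        tree = Phylogeny.from_newick(TREE4)
        assert aggregate({}, tree)["empty"]

    def test_recovers_planted_history_correlation(self):
        """Total inferred endpoint events per branch correlate with the true
        endpoint-change counts of planted trait histories (two independent
        characters simulated per gene, as for GA- and SP-bias)."""
        from genbias.syndata import simulate_trait_history

        tree = Phylogeny.from_newick(TREE4)
        rng = np.random.default_rng(2)
        true_counts, inferred = {}, {}
        for trait, (q01, q10) in (("GA", (0.9, 1.2)), ("SP", (0.5, 0.7))):
            for b in tree.branch_ids:
                true_counts[(trait, b)] = 0
            table = {}
            for g in range(500):
                hist = simulate_trait_history(tree, q01, q10, 0.3, rng)
                for c, u in tree.parent.items():
                    if hist[c] != hist[u]:
                        true_counts[(trait, tree.branch_id[c])] += 1
                table[f"g{g}"] = {l: hist[i] for l, i in tree.leaf_index.items()}
            results = fit_and_map_genes(tree, table, n_maps=100, seed=5, pooled=True)
            agg = aggregate(results, tree)
            for b in tree.branch_ids:
                inferred[(trait, b)] = (
                    agg["branch_totals"][b]["gain"] + agg["branch_totals"][b]["loss"]
                )
        keys = sorted(true_counts)
        rho, _ = stats.spearmanr(
            [true_counts[k] for k in keys], [inferred[k] for k in keys]
        )
        assert rho > 0.8
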