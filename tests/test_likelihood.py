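import numpy as np
import pytest

from phyloquartet.alignment import MISSING, Alignment
from phyloquartet.likelihood import (QuartetEngine, TreeLikelihood,
                                     UninformativeQuartetError,
                                     _compress_columns, brute_force_lnL,
                                     optimize_quartet, site_log_likelihoods)
from phyloquartet.simulate import simulate_gene
from phyloquartet.trees import PhyloTree, quartet_tree, random_tree


def _random_instance(rng, model, n_leaves, n_sites, with_missing):
    labels = [f"t{i}" for i in range(n_leaves)]
    tree = random_tree(labels, rng)
    data = rng.integers(0, 20, size=(n_leaves, n_sites)).astype(np.uint8)
    if with_missing:
        data[rng.integers(n_leaves), rng.integers(n_sites)] = MISSING
    return tree, Alignment(labels, data)


class TestPruningAgainstEnumeration:
    @pytest.mark.parametrize("n_leaves,gamma,with_missing", [
        (4, False, False), (4, True, True), (5, False, True),
        (5, True, False), (6, False, False),
    ])
    def test_matches_brute_force(self, rng, poisson, poisson_gamma, empirical,
                                 n_leaves, gamma, with_missing):
        """Felsenstein pruning equals explicit summation over all
        internal-node state assignments."""
        model = {(False,): poisson, (True,): poisson_gamma}[(gamma,)]
        for m in (model, empirical) if not gamma else (model,):
            tree, aln = _random_instance(rng, m, n_leaves, 2, with_missing)
            bf = brute_force_lnL(tree, aln, m)
            pr = TreeLikelihood(tree, aln, m).total_log_likelihood()
            assert abs(bf - pr) < 1e-8

    def test_two_leaf_closed_form(self, empirical):
        """lnL of two residues at distance t is ln(pi_i P_ij(t))."""
        aln = Alignment(["x", "y"], np.array([[3], [11]], dtype=np.uint8))
        tree = PhyloTree.from_newick("(x:0.15,y:0.1);")
        expect = np.log(empirical.freqs[3] * empirical.transition(0.25)[3, 11])
        got = TreeLikelihood(tree, aln, empirical).total_log_likelihood()
        assert abs(got - expect) < 1e-10

    def test_brute_force_refuses_large_trees(self, rng, poisson):
        tree, aln = _random_instance(rng, poisson, 7, 1, False)
        with pytest.raises(ValueError, match="6 leaves"):
            brute_force_lnL(tree, aln, poisson)


class TestLikelihoodInvariances:
    def test_all_missing_site_has_lnL_zero(self, poisson):
        aln = Alignment(list("abcd"), np.full((4, 1), MISSING, dtype=np.uint8))
        tree = quartet_tree("abcd", [0.1] * 5)
        assert abs(site_log_likelihoods(tree, aln, poisson)[0]) < 1e-12

    def test_rerooting_invariance(self, rng, empirical_gamma):
        tree, aln = _random_instance(rng, empirical_gamma, 6, 30, True)
        base = TreeLikelihood(tree, aln, empirical_gamma).total_log_likelihood()
        for n in tree.postorder():
            if not n.is_leaf and n is not tree.root:
                alt = TreeLikelihood(tree.reroot_at(n), aln,
                                     empirical_gamma).total_log_likelihood()
                assert abs(alt - base) < 1e-8

    def test_leaf_order_invariance(self, rng, poisson):
        tree, aln = _random_instance(rng, poisson, 5, 20, False)
        base = TreeLikelihood(tree, aln, poisson).total_log_likelihood()
        shuffled = aln.subset_taxa(list(reversed(aln.labels)))
        assert abs(TreeLikelihood(tree, shuffled, poisson).total_log_likelihood()
                   - base) < 1e-12

    def test_zero_length_branch_equals_contraction(self, poisson):
        """A zero-length internal branch is indistinguishable from the
        multifurcation obtained by contracting it."""
        aln = Alignment(list("abcd"),
                        np.array([[1, 2], [1, 5], [7, 2], [7, 9]], dtype=np.uint8))
        t_zero = PhyloTree.from_newick("(a:0.1,b:0.2,(c:0.3,d:0.4):0.0);")
        t_flat = PhyloTree.from_newick("(a:0.1,b:0.2,c:0.3,d:0.4);")
        l1 = TreeLikelihood(t_zero, aln, poisson).total_log_likelihood()
        l2 = TreeLikelihood(t_flat, aln, poisson).total_log_likelihood()
        assert abs(l1 - l2) < 1e-10
        assert abs(brute_force_lnL(t_zero, aln, poisson) - l1) < 1e-8

    def test_site_lnls_sum_to_total(self, rng, poisson_gamma):
        tree, aln = _random_instance(rng, poisson_gamma, 5, 40, True)
        eng = TreeLikelihood(tree, aln, poisson_gamma)
        assert abs(eng.site_log_likelihoods().sum()
                   - eng.total_log_likelihood()) < 1e-9


class TestQuartetOptimization:
    def test_engine_matches_pruning_at_fixed_lengths(self, rng, empirical_gamma):
        data = rng.integers(0, 20, size=(4, 200)).astype(np.uint8)
        aln = Alignment(list("abcd"), data)
        t = [0.15, 0.3, 0.08, 0.2, 0.6]
        ref = TreeLikelihood(quartet_tree("abcd", t), aln,
                             empirical_gamma).total_log_likelihood()
        pats, counts, _ = _compress_columns(data)
        eng = QuartetEngine(pats, counts, empirical_gamma)
        eng.t = np.array(t)
        assert abs(eng.log_likelihood() - ref) < 1e-8

    def test_identical_sisters_hit_lower_bound(self, poisson, rng):
        shared = rng.integers(0, 20, size=300).astype(np.uint8)
        other = rng.integers(0, 20, size=(2, 300)).astype(np.uint8)
        aln = Alignment(list("abcd"), np.vstack([shared, shared, other]))
        lengths, _ = optimize_quartet(aln, (("a", "b"), ("c", "d")), poisson)
        assert lengths[0] < 1e-3 and lengths[1] < 1e-3

    def test_optimization_never_decreases_lnl(self, rng, poisson):
        data = rng.integers(0, 20, size=(4, 400)).astype(np.uint8)
        pats, counts, _ = _compress_columns(data)
        eng = QuartetEngine(pats, counts, poisson)
        vals = [eng.log_likelihood()]
        for _ in range(5):
            vals.append(eng.optimize(tol=-1.0, max_sweeps=1))
        assert all(b >= a - 1e-9 for a, b in zip(vals, vals[1:]))

    def test_internal_branch_recovery(self, poisson):
        """Simulation on (a,b|c,d) with internal branch 0.3 and 10,000 sites
        recovers the internal branch within 10% and prefers the true split."""
        tree = quartet_tree("abcd", [0.2, 0.2, 0.3, 0.2, 0.2])
        aln = simulate_gene(tree, poisson, 10_000, seed=20260923)
        lengths, lnl_true = optimize_quartet(aln, (("a", "b"), ("c", "d")), poisson)
        assert abs(lengths[2] - 0.3) / 0.3 < 0.10
        for alt in ((("a", "c"), ("b", "d")), (("a", "d"), ("b", "c"))):
            _, lnl_alt = optimize_quartet(aln, alt, poisson)
            assert lnl_true > lnl_alt

    def test_uninformative_quartet_raises(self, poisson):
        data = np.full((4, 10), MISSING, dtype=np.uint8)
        data[0, :] = 1  # no column has all four present
        aln = Alignment(list("abcd"), data)
        with pytest.raises(UninformativeQuartetError):
            optimize_quartet(aln, (("a", "b"), ("c", "d")), poisson)

    def test_label_mismatch_rejected(self, poisson, rng):
        aln = Alignment(list("abcd"),
                        rng.integers(0, 20, size=(4, 50)).astype(np.uint8))
        with pytest.raises(ValueError):
            optimize_quartet(aln, (("a", "b"), ("c", "z")), poisson)


class TestGeneralBranchOptimization:
    def test_monotone_and_reaches_better_lnl(self, rng, poisson):
        labels = [f"t{i}" for i in range(8)]
        tree = random_tree(labels, rng, 0.05, 0.3)
        aln = simulate_gene(tree, poisson, 300, seed=4)
        # start from perturbed lengths
        for n in tree.postorder():
            if n is not tree.root:
                n.length = 0.1
        eng = TreeLikelihood(tree, aln, poisson)
        before = eng.total_log_likelihood()
        after = eng.optimize_branch_lengths(tol=1e-5, max_sweeps=30)
        assert after >= before
        assert abs(eng.total_log_likelihood() - after) < 1e-6
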