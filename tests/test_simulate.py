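import numpy as np
import pytest

from phyloquartet.alignment import MISSING
from phyloquartet.simulate import (HeterogeneitySpec, MissingnessSpec,
                                   OutlierSpec, apply_missingness,
                                   inject_outliers, make_fourgroup_fixture,
                                   simulate_gene, simulate_nonstationary)
from phyloquartet.trees import PhyloTree

STAR4 = "(a:0.000001,b:0.000001,(c:0.000001,d:0.000001):0.000001);"


class TestSimulateGene:
    def test_deterministic_under_seed(self, poisson):
        t = PhyloTree.from_newick("(a:0.1,b:0.2,(c:0.1,d:0.3):0.1);")
        assert simulate_gene(t, poisson, 500, 42) == simulate_gene(t, poisson, 500, 42)

    def test_tiny_branches_give_identical_sequences(self, poisson):
        aln = simulate_gene(PhyloTree.from_newick(STAR4), poisson, 1000, 7)
        ident = (aln.data == aln.data[0]).all(axis=0).mean()
        assert ident >= 0.99

    def test_residue_frequencies_match_pi(self, empirical):
        """Observed frequencies over many sites stay within 3 binomial SDs
        of the model's stationary frequencies."""
        t = PhyloTree.from_newick("(a:0.2,b:0.2,(c:0.2,d:0.2):0.2);")
        aln = simulate_gene(t, empirical, 30_000, 3)
        # rows are correlated through shared ancestry; test one row, whose
        # sites are independent draws with marginal pi
        row = aln.row("a")
        obs = np.bincount(row, minlength=21)[:20] / row.size
        sd = np.sqrt(empirical.freqs * (1 - empirical.freqs) / row.size)
        assert (np.abs(obs - empirical.freqs) < 3.5 * sd + 1e-9).all()

    def test_rejects_zero_length(self, poisson):
        with pytest.raises(ValueError):
            simulate_gene(PhyloTree.from_newick(STAR4), poisson, 0, 1)


class TestNonstationary:
    def test_identity_shift_reproduces_stationary_stream(self, poisson):
        t = PhyloTree.from_newick("(a:0.3,b:0.3,(c:0.4,d:0.4):0.2);")
        het = HeterogeneitySpec({"c", "d"}, np.full(20, 0.05))
        assert simulate_nonstationary(t, poisson, het, 400, 11) == \
            simulate_gene(t, poisson, 400, 11)

    def test_shift_confined_to_affected_clade(self, poisson):
        pi2 = np.full(20, 0.5 / 18)
        pi2[:2] = 0.25
        t = PhyloTree.from_newick("(a:0.3,b:0.3,(c:0.6,d:0.6):0.3);")
        aln = simulate_nonstationary(t, poisson,
                                     HeterogeneitySpec({"c", "d"}, pi2), 6000, 5)
        frac = {lab: (aln.row(lab) < 2).mean() for lab in "abcd"}
        assert frac["c"] > 0.2 and frac["d"] > 0.2
        assert frac["a"] < 0.15 and frac["b"] < 0.15

    def test_terminal_only_shift(self, poisson):
        pi2 = np.full(20, 0.5 / 18)
        pi2[:2] = 0.25
        t = PhyloTree.from_newick("(a:0.3,b:0.3,(c:0.8,d:0.8):0.3);")
        aln = simulate_nonstationary(t, poisson,
                                     HeterogeneitySpec({"c"}, pi2), 6000, 5)
        assert (aln.row("c") < 2).mean() > 0.2
        assert (aln.row("d") < 2).mean() < 0.15

    def test_unknown_taxon_rejected(self, poisson):
        t = PhyloTree.from_newick(STAR4)
        with pytest.raises(KeyError):
            simulate_nonstationary(t, poisson,
                                   HeterogeneitySpec({"zz"}, np.full(20, 0.05)),
                                   100, 1)


class TestMissingness:
    def _genes(self, poisson, n_genes=30, n_taxa=10, length=50, seed=2):
        labels = [f"s{i}" for i in range(n_taxa)]
        t = PhyloTree.from_newick(
            "(" + ",".join(f"{lab}:0.1" for lab in labels) + ");")
        return [(f"g{i}", simulate_gene(t, poisson, length, seed + i))
                for i in range(n_genes)]

    def test_probability_one_is_identity(self, poisson):
        genes = self._genes(poisson, n_genes=5)
        out, presence = apply_missingness(genes, MissingnessSpec(1.0), 0)
        assert all(a == b for (_, a), (_, b) in zip(genes, out))
        assert presence.to_numpy().all()

    def test_realized_fraction_within_3sd(self, poisson):
        genes = self._genes(poisson, n_genes=50, n_taxa=20, length=10)
        _, presence = apply_missingness(genes, MissingnessSpec(0.8), 3)
        n = presence.size
        sd = np.sqrt(0.8 * 0.2 / n)
        assert abs(presence.to_numpy().mean() - 0.8) < 3 * sd

    def test_explicit_matrix_is_honoured_exactly(self, poisson):
        import pandas as pd
        genes = self._genes(poisson, n_genes=3, n_taxa=4)
        species = sorted({lab for _, a in genes for lab in a.labels})
        want = pd.DataFrame(True, index=species, columns=[g for g, _ in genes])
        want.iloc[0, 0] = False
        want.iloc[2, 1] = False
        out, presence = apply_missingness(
            genes, MissingnessSpec(presence_matrix=want), 0)
        assert presence.equals(want)
        assert species[0] not in dict(out)["g0"].labels

    def test_presence_matrix_equals_realized_pattern(self, poisson):
        genes = self._genes(poisson, n_genes=20, n_taxa=8)
        out, presence = apply_missingness(genes, MissingnessSpec(0.6), 9)
        for g, aln in out:
            for sp in presence.index:
                assert presence.at[sp, g] == aln.has_taxon(sp)


class TestOutliers:
    def test_zero_outliers_is_identity(self, poisson):
        genes = TestMissingness()._genes(poisson, n_genes=4)
        out, truth = inject_outliers(genes, OutlierSpec(0), 1, model=poisson)
        assert truth == [] and all(a == b for (_, a), (_, b) in zip(genes, out))

    def test_truth_list_matches_request(self, poisson):
        genes = TestMissingness()._genes(poisson, n_genes=10)
        out, truth = inject_outliers(
            genes, OutlierSpec(n_genes=4, n_sequences_per_gene=2), 5,
            model=poisson)
        assert len(truth) == 8
        assert len({g for g, _ in truth}) == 4
        for g, taxon in truth:
            assert not (dict(out)[g].row(taxon) == dict(genes)[g].row(taxon)).all()

    def test_shuffled_row_loses_similarity(self, poisson):
        """A shuffled row in a conserved gene has lower mean pairwise
        identity than any intact row."""
        t = PhyloTree.from_newick(
            "(" + ",".join(f"s{i}:0.02" for i in range(8)) + ");")
        aln = simulate_gene(t, poisson, 400, 6)
        out, truth = inject_outliers([("g", aln)], OutlierSpec(1, 1, "shuffle"), 3)
        bad = truth[0][1]
        mod = out[0][1]

        def mean_ident(lab):
            row = mod.row(lab)
            return np.mean([(row == mod.row(o)).mean()
                            for o in mod.labels if o != lab])
        idents = {lab: mean_ident(lab) for lab in mod.labels}
        assert min(idents, key=idents.get) == bad


class TestFourGroupFixture:
    def test_reproducible_and_truth_consistent(self, poisson):
        fx1 = make_fourgroup_fixture(n_genes=8, gene_length=100, seed=3,
                                     conflict_rho=0.5, model=poisson)
        fx2 = make_fourgroup_fixture(n_genes=8, gene_length=100, seed=3,
                                     conflict_rho=0.5, model=poisson)
        assert all(a == b and x == y
                   for (x, a), (y, b) in zip(fx1.genes, fx2.genes))
        assert fx1.truth.equals(fx2.truth)
        assert set(fx1.truth.topology) <= {"T1", "T2", "T3"}

    def test_rho_zero_is_all_concordant(self, poisson):
        fx = make_fourgroup_fixture(n_genes=10, gene_length=60, seed=1,
                                    model=poisson)
        assert (fx.truth.topology == "T1").all()

    def test_star_fixture(self, poisson):
        fx = make_fourgroup_fixture(n_genes=4, gene_length=60, seed=2,
                                    star=True, model=poisson)
        assert (fx.truth.topology == "star").all()

    def test_invalid_rho_rejected(self, poisson):
        with pytest.raises(ValueError):
            make_fourgroup_fixture(conflict_rho=1.5, model=poisson)
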