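import numpy as np
import pandas as pd
import pytest

from phyloquartet.alignment import MISSING, Alignment
from phyloquartet.curation import (AssemblyScore, DatasetTier,
                                   GroupDefinitions, compile_dataset,
                                   completeness, concatenate,
                                   detect_outlier_sequences, drop_taxa,
                                   filter_genes_by_coverage,
                                   filter_species_by_coverage,
                                   mask_ambiguous_sites, rank_assemblies)
from phyloquartet.simulate import OutlierSpec, inject_outliers, simulate_gene
from phyloquartet.trees import PhyloTree


class TestAssemblyRanking:
    def test_length_dominates_gene_count(self):
        scores = [AssemblyScore("sp", "A", 1500, 450_000),
                  AssemblyScore("sp", "B", 1600, 440_000)]
        assert rank_assemblies(scores) == {"sp": "A"}

    def test_single_assembly(self):
        assert rank_assemblies([AssemblyScore("sp", "only", 10, 100)]) == \
            {"sp": "only"}

    def test_tie_breaks(self):
        scores = [AssemblyScore("sp", "z", 10, 100),
                  AssemblyScore("sp", "a", 10, 100),
                  AssemblyScore("sp", "m", 11, 100)]
        # equal length: higher gene count wins; full tie: lexicographic id
        assert rank_assemblies(scores) == {"sp": "m"}
        assert rank_assemblies(scores[:2]) == {"sp": "a"}

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rank_assemblies([])


class TestCoverageFilters:
    def _table(self, cover):
        """genes x species boolean frame with given per-species coverage
        out of 100 orthologs."""
        return pd.DataFrame({sp: [i < int(c * 100) for i in range(100)]
                             for sp, c in cover.items()})

    def test_species_below_60pct_excluded(self):
        table = self._table({"ok": 0.8, "low": 0.47})
        retained, excluded = filter_species_by_coverage(table, 100)
        assert retained == ["ok"]
        assert excluded == {"low": pytest.approx(0.47)}

    def test_species_at_exact_boundary_retained(self):
        """Exclusion applies to species with *less than* 60% coverage."""
        table = self._table({"edge": 0.60})
        retained, excluded = filter_species_by_coverage(table, 100)
        assert retained == ["edge"] and not excluded

    def test_gene_boundary_at_least_half(self):
        presence = pd.DataFrame(
            [[True] * 29 + [False] * 29,   # exactly 50% of 58 species
             [True] * 28 + [False] * 30],  # 48%
            index=["g_half", "g_less"],
            columns=[f"s{i}" for i in range(58)])
        assert filter_genes_by_coverage(presence) == ["g_half"]

    def test_threshold_one_equals_strict(self):
        presence = pd.DataFrame([[True, True], [True, False]],
                                index=["g_full", "g_part"], columns=["a", "b"])
        assert filter_genes_by_coverage(presence, threshold=1.0) == ["g_full"]


class TestOutlierDetection:
    def test_identical_rows_never_flagged(self):
        aln = Alignment.from_strings({f"s{i}": "ACDEFGHIK" for i in range(6)})
        assert detect_outlier_sequences(aln) == []

    def test_too_few_sequences_warns(self):
        aln = Alignment.from_strings({"a": "ACD", "b": "ACD", "c": "ACD"})
        with pytest.warns(UserWarning):
            assert detect_outlier_sequences(aln) == []

    def test_shuffled_row_flagged(self, poisson, rng):
        t = PhyloTree.from_newick(
            "(" + ",".join(f"s{i}:0.03" for i in range(11)) + ");")
        aln = simulate_gene(t, poisson, 300, 8)
        genes, truth = inject_outliers([("g", aln)],
                                       OutlierSpec(1, 1, "shuffle"), 12)
        flags = detect_outlier_sequences(genes[0][1])
        assert flags == [truth[0][1]]


class TestMasking:
    def test_conserved_alignment_untouched(self):
        aln = Alignment.from_strings(
            {f"s{i}": "ACDEFGHIKLMNPQRSTVWY" * 3 for i in range(6)})
        assert mask_ambiguous_sites(aln, seed=1).size == 0

    def test_gap_only_column_always_removed(self):
        seqs = {f"s{i}": "ACDEFGHIKL" + "-" + "MNPQRSTVWY" for i in range(6)}
        masked = mask_ambiguous_sites(Alignment.from_strings(seqs), seed=1)
        assert 10 in masked.tolist()

    def test_random_block_masked_core_kept(self, poisson, rng):
        """Conserved core plus an appended iid-random block: most random
        columns masked, almost no core columns masked."""
        t = PhyloTree.from_newick(
            "(" + ",".join(f"s{i}:0.02" for i in range(8)) + ");")
        core = simulate_gene(t, poisson, 150, 3)
        noise = rng.integers(0, 20, size=(8, 80)).astype(np.uint8)
        aln = Alignment(core.labels, np.hstack([core.data, noise]))
        masked = mask_ambiguous_sites(aln, seed=5)
        frac_noise = np.isin(np.arange(150, 230), masked).mean()
        frac_core = np.isin(np.arange(150), masked).mean()
        assert frac_noise >= 0.8
        assert frac_core <= 0.05


class TestConcatenation:
    def _genes(self, poisson):
        t = PhyloTree.from_newick("(a:0.1,b:0.1,(c:0.1,d:0.1):0.05);")
        g1 = simulate_gene(t, poisson, 100, 1)
        g2 = simulate_gene(t, poisson, 50, 2).drop_taxa(["d"])
        return [("g1", g1), ("g2", g2)]

    def test_width_partitions_and_missing_fill(self, poisson):
        sm = concatenate(self._genes(poisson))
        assert sm.alignment.n_sites == 150
        assert [(p.name, p.start, p.end) for p in sm.partitions] == \
            [("g1", 0, 100), ("g2", 100, 150)]
        assert (sm.alignment.row("d")[100:] == MISSING).all()
        assert (sm.alignment.row("d")[:100] != MISSING).any()

    def test_round_trip_by_partition_slicing(self, poisson):
        genes = self._genes(poisson)
        sm = concatenate(genes)
        g1_back = sm.gene("g1").subset_taxa(genes[0][1].labels)
        assert g1_back == genes[0][1]

    def test_duplicate_gene_names_rejected(self, poisson):
        genes = self._genes(poisson)
        with pytest.raises(ValueError, match="[Dd]uplicate"):
            concatenate([genes[0], genes[0]])

    def test_drop_taxa(self, poisson):
        genes = self._genes(poisson)
        out = drop_taxa(genes, ["d"])
        assert all(not aln.has_taxon("d") for _, aln in out)
        with pytest.raises(KeyError):
            drop_taxa(genes, ["nope"])


class TestTiers:
    def _fixture(self, poisson):
        t = PhyloTree.from_newick("(a:0.1,b:0.1,(c:0.1,d:0.1):0.05);")
        genes = []
        for i in range(10):
            g = simulate_gene(t, poisson, 20, i)
            if i < 2:
                g = g.drop_taxa(["d"])     # strict excludes these
            genes.append((f"g{i}", g))
        return concatenate(genes)

    def test_strict_has_full_coverage(self, poisson):
        sm = self._fixture(poisson)
        strict = compile_dataset(sm, "strict")
        assert len(strict.partitions) == 8
        assert not strict.alignment.missing_mask().all(axis=1).any()
        presence = strict.gene_presence()
        assert presence.all()

    def test_tier_nesting(self, poisson):
        sm = self._fixture(poisson)
        groups = GroupDefinitions({"G1": ["a", "b"], "G2": ["c", "d"]})
        names = {t: set(compile_dataset(sm, t, groups).partitions.names)
                 for t in ("strict", "intermediate", "unreduced")}
        assert names["strict"] <= names["intermediate"] <= names["unreduced"]
        assert len(names["unreduced"]) == 10

    def test_gene_missing_whole_group_excluded_from_intermediate(self, poisson):
        t = PhyloTree.from_newick("(a:0.1,b:0.1,(c:0.1,d:0.1):0.05);")
        g_ok = simulate_gene(t, poisson, 20, 0)
        g_bad = simulate_gene(t, poisson, 20, 1).drop_taxa(["c", "d"])
        sm = concatenate([("ok", g_ok), ("bad", g_bad)])
        groups = GroupDefinitions({"G1": ["a", "b"], "G2": ["c", "d"]})
        inter = compile_dataset(sm, DatasetTier.INTERMEDIATE, groups)
        assert inter.partitions.names == ["ok"]

    def test_intermediate_without_groups_rejected(self, poisson):
        with pytest.raises(ValueError):
            compile_dataset(self._fixture(poisson), "intermediate")


class TestCompleteness:
    def test_full_matrix(self, poisson):
        t = PhyloTree.from_newick("(a:0.1,b:0.1,(c:0.1,d:0.1):0.05);")
        sm = concatenate([("g", simulate_gene(t, poisson, 50, 1))])
        rep = completeness(sm)
        assert rep.overall_completeness == 1.0
        assert (rep.pairwise_shared.to_numpy() == 1.0).all()

    def test_ca_arithmetic(self):
        data = np.zeros((2, 10), dtype=np.uint8)
        data[0, :2] = MISSING  # 2 of 20 cells missing
        sm = concatenate([("g", Alignment(["a", "b"], data))])
        rep = completeness(sm)
        assert rep.overall_completeness == pytest.approx(0.9)
        assert rep.pairwise_shared.loc["a", "b"] == pytest.approx(0.8)


class TestAssemblyScoreIO:
    def test_read_assembly_scores_round_trip(self, tmp_path):
        import pandas as pd
        from phyloquartet.curation import read_assembly_scores
        df = pd.DataFrame([
            {"species": "sp1", "assembly_id": "A", "genes_assigned": 1500,
             "cumulative_length": 450000},
            {"species": "sp1", "assembly_id": "B", "genes_assigned": 1600,
             "cumulative_length": 440000},
        ])
        path = tmp_path / "scores.tsv"
        df.to_csv(path, sep="\t", index=False)
        scores = read_assembly_scores(path)
        assert rank_assemblies(scores) == {"sp1": "A"}

    def test_missing_columns_rejected(self, tmp_path):
        import pandas as pd
        from phyloquartet.curation import read_assembly_scores
        path = tmp_path / "bad.tsv"
        pd.DataFrame({"species": ["x"]}).to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="columns"):
            read_assembly_scores(path)
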