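import numpy as np
import pytest

from pheromat import seqio, synth
from pheromat.alpha import annotate_repeats
from pheromat.motifs import find_gy_motif, st_fraction, terminal_caax_class


class TestAlphaGenerator:
    def test_round_trip_at_bounds(self):
        """Planted repeats are recovered at both ends of the documented range."""
        for n in (2, 18):
            rng = np.random.default_rng(n)
            rep = synth.sample_repeat(rng)
            g = synth.gen_alpha_gene(rep, n, rng)
            ann = annotate_repeats(g.protein)
            assert ann.n_repeats == n
            assert set(ann.repeat_sequences) == {rep}

    def test_gene_model_translates_to_protein(self):
        g = synth.gen_alpha_gene("WCGRPGQPC", 4, seed=5, intron_probability=1.0)
        assert len(g.gene.exons) == 2  # intron present
        prot = seqio.extract_cds_and_translate({g.contig.id: g.contig}, g.gene)
        assert prot.residues == g.protein

    def test_minus_strand_gene(self):
        g = synth.gen_alpha_gene("WCGRPGQPC", 3, seed=6, strand="-")
        prot = seqio.extract_cds_and_translate({g.contig.id: g.contig}, g.gene)
        assert prot.residues == g.protein

    def test_zero_repeats_rejected(self):
        with pytest.raises(ValueError):
            synth.gen_alpha_gene("WCGRPGQPC", 0, seed=1)

    def test_seed_determinism(self):
        a = synth.gen_alpha_gene("WCGRPGQPC", 3, seed=9)
        b = synth.gen_alpha_gene("WCGRPGQPC", 3, seed=9)
        assert a.contig.residues == b.contig.residues
        assert a.gene.exons == b.gene.exons

    def test_sampled_repeats_respect_grammar(self, rng):
        for _ in range(50):
            rep = synth.sample_repeat(rng)
            assert 9 <= len(rep) <= 14
            assert rep[1] not in "AP"
            assert rep[-1] not in "KR"
            assert not any(rep[i : i + 2] in ("KR", "RR", "KK") for i in range(len(rep) - 1))


class TestAFactorGenerator:
    def test_filter_flags_round_trip(self):
        g = synth.gen_afactor_gene(50, "CTVM", st_rich=True, gy=True, seed=3)
        assert len(g.protein) == 50
        assert terminal_caax_class(g.protein) in ("CAAX", "CPAX")
        assert st_fraction(g.protein, 20) >= 0.30
        assert find_gy_motif(g.protein) is not None

    def test_negative_control_length(self):
        g = synth.gen_afactor_gene(101, "CTVM", True, True, seed=4)
        assert len(g.protein) == 101  # filtered out downstream

    def test_invalid_box_rejected(self):
        with pytest.raises(ValueError):
            synth.build_afactor_protein(50, "AAAA", True, True, np.random.default_rng(0))

    def test_seed_determinism(self):
        a = synth.gen_afactor_gene(seed=8)
        b = synth.gen_afactor_gene(seed=8)
        assert a.contig.residues == b.contig.residues

    def test_no_gy_when_disabled(self):
        g = synth.gen_afactor_gene(60, "CSVM", st_rich=False, gy=False, seed=5)
        assert find_gy_motif(g.protein) is None


class TestMatArchitectureGenerator:
    def test_unknown_name_lists_valid(self):
        with pytest.raises(ValueError, match="het_MAT1_1"):
            synth.gen_mat_architecture("nonsense", seed=1)

    def test_split_architecture_has_two_contigs(self):
        arch = synth.gen_mat_architecture("split_mixed", seed=1)
        assert len(arch.contigs) == 2

    def test_truth_names_expected_strategy(self):
        for name in synth.MAT_ARCHITECTURES:
            arch = synth.gen_mat_architecture(name, seed=2)
            assert arch.truth["expected_strategy"] == synth.ARCHITECTURE_STRATEGY[name]

    def test_seed_determinism(self):
        a = synth.gen_mat_architecture("fused_homothallic", seed=3)
        b = synth.gen_mat_architecture("fused_homothallic", seed=3)
        assert [c.residues for c in a.contigs] == [c.residues for c in b.contigs]


class TestTreeAndStates:
    def test_tree_has_requested_tips(self):
        from pheromat.asr import PhyloTree

        tree = PhyloTree.from_newick(synth.gen_tree(20, seed=4))
        assert len(tree.leaves) == 20

    def test_clustered_state_split(self):
        from pheromat.asr import PhyloTree

        tree = PhyloTree.from_newick(synth.gen_tree(50, seed=6))
        states = synth.assign_clustered_states(tree, n_hom=8, n_unknown=5, seed=6)
        counts = {s: list(states.values()).count(s) for s in "01?"}
        assert counts == {"0": 8, "1": 37, "?": 5}

    def test_cohort_determinism_and_validity(self):
        c1 = synth.gen_cohort(6, seed=12, state_split=(4, 1, 1))
        c2 = synth.gen_cohort(6, seed=12, state_split=(4, 1, 1))
        assert c1.newick == c2.newick
        assert c1.states == c2.states
        assert [g.genome_id for g in c1.genomes] == [g.genome_id for g in c2.genomes]
        assert c1.genomes[0].contigs[0].residues == c2.genomes[0].contigs[0].residues
        # outputs are format-valid
        for g in c1.genomes:
            for contig in g.contigs:
                assert set(contig.residues) <= set("ACGT")
            for gene in g.genes:
                contig = {c.id: c for c in g.contigs}[gene.contig_id]
                assert gene.end <= len(contig)

    def test_bad_split_rejected(self):
        with pytest.raises(ValueError):
            synth.gen_cohort(6, seed=1, state_split=(4, 4, 4))


class TestCountTableGenerator:
    def test_valid_table(self):
        from pheromat.expression import CountTable

        df = synth.gen_count_table(3)
        table = CountTable(df)  # validates
        assert set(df["mating_type"]) == {"MAT1-1", "MAT1-2", "mixed"}
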