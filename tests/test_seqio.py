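import pytest

from pheromat import seqio, synth
from pheromat.seqio import GeneModel, SequenceRecord


class TestFasta:
    def test_single_record(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">a\nACGT\n")
        recs = seqio.read_fasta(p)
        assert len(recs) == 1
        assert recs[0].id == "a" and recs[0].residues == "ACGT"

    def test_two_records_in_order(self, tmp_path):
        p = tmp_path / "b.fa"
        p.write_text(">x\nACGT\nACGT\n>y\nTTTT\n")
        recs = seqio.read_fasta(p)
        assert [r.id for r in recs] == ["x", "y"]
        assert recs[0].residues == "ACGTACGT"

    def test_empty_file_warns(self, tmp_path, caplog):
        p = tmp_path / "empty.fa"
        p.write_text("")
        with caplog.at_level("WARNING"):
            assert seqio.read_fasta(p) == []
        assert "no records" in caplog.text

    def test_empty_sequence_raises(self, tmp_path):
        p = tmp_path / "bad.fa"
        p.write_text(">a\n>b\nACGT\n")
        with pytest.raises(seqio.FastaFormatError):
            seqio.read_fasta(p)

    def test_round_trip(self, tmp_path, rng):
        recs = [
            SequenceRecord(f"c{i}", synth.random_dna(int(rng.integers(10, 200)), rng))
            for i in range(5)
        ]
        p = tmp_path / "rt.fa"
        seqio.write_fasta(recs, p)
        back = seqio.read_fasta(p)
        assert [(r.id, r.residues) for r in back] == [(r.id, r.residues) for r in recs]


class TestGff3:
    GFF = (
        "##gff-version 3\n"
        "ctg1\tsrc\tgene\t1\t172\t.\t+\t.\tID=g1\n"
        "ctg1\tsrc\tmRNA\t1\t172\t.\t+\t.\tID=m1;Parent=g1\n"
        "ctg1\tsrc\tCDS\t1\t30\t.\t+\t0\tID=c1;Parent=m1\n"
        "ctg1\tsrc\tCDS\t100\t172\t.\t+\t0\tID=c2;Parent=m1\n"
    )

    def test_coordinate_conversion_two_exons(self, tmp_path):
        p = tmp_path / "g.gff"
        p.write_text(self.GFF)
        genes = seqio.read_gff3(p)
        assert len(genes) == 1
        assert genes[0].exons == [(0, 30), (99, 172)]
        assert genes[0].strand == "+"

    def test_single_cds_conversion(self, tmp_path):
        p = tmp_path / "g.gff"
        p.write_text(
            "##gff-version 3\n"
            "ctg1\tsrc\tgene\t1\t9\t.\t+\t.\tID=g1\n"
            "ctg1\tsrc\tCDS\t1\t9\t.\t+\t0\tParent=g1\n"
        )
        assert seqio.read_gff3(p)[0].exons == [(0, 9)]

    def test_end_before_start_rejected(self, tmp_path):
        p = tmp_path / "g.gff"
        p.write_text("##gff-version 3\nctg1\tsrc\tgene\t30\t10\t.\t+\t.\tID=g1\n")
        with pytest.raises(seqio.GffFormatError, match="end"):
            seqio.read_gff3(p)

    def test_unknown_contig_named_in_error(self, tmp_path):
        p = tmp_path / "g.gff"
        p.write_text(self.GFF)
        with pytest.raises(seqio.GffFormatError, match="ctg1"):
            seqio.read_gff3(p, contig_lengths={"other": 5000})

    def test_orphan_cds_rejected(self, tmp_path):
        p = tmp_path / "g.gff"
        p.write_text("##gff-version 3\nctg1\tsrc\tCDS\t1\t9\t.\t+\t0\tParent=ghost\n")
        with pytest.raises(seqio.GffFormatError):
            seqio.read_gff3(p)

    def test_locus_tag_dialect_accepted(self, tmp_path):
        p = tmp_path / "g.gff"
        p.write_text(
            "##gff-version 3\n"
            "ctg1\tsrc\tgene\t1\t9\t.\t+\t.\tlocus_tag=LT1\n"
            "ctg1\tsrc\tCDS\t1\t9\t.\t+\t0\tlocus_tag=LT1\n"
        )
        assert seqio.read_gff3(p)[0].gene_id == "LT1"

    def test_write_read_round_trip(self, tmp_path):
        genes = [GeneModel("g1", "ctg1", "-", [(10, 40), (100, 160)], "ste2")]
        p = tmp_path / "rt.gff"
        seqio.write_gff3(genes, p)
        assert p.read_text().startswith("##gff-version 3")
        back = seqio.read_gff3(p)
        assert back[0].exons == genes[0].exons
        assert back[0].strand == "-"
        assert back[0].tag == "ste2"


class TestTranslate:
    def test_simple_cds(self):
        genome = [SequenceRecord("c", "ATGGCTTAA")]
        gene = GeneModel("g", "c", "+", [(0, 9)])
        assert seqio.extract_cds_and_translate(genome, gene).residues == "MA"

    def test_minus_strand_symmetry(self):
        # reverse complement of ATGGCTTAA placed on the minus strand
        genome = [SequenceRecord("c", seqio.revcomp("ATGGCTTAA"))]
        gene = GeneModel("g", "c", "-", [(0, 9)])
        assert seqio.extract_cds_and_translate(genome, gene).residues == "MA"

    def test_internal_stop_flagged(self):
        genome = [SequenceRecord("c", "ATGTAAGCTTAA")]
        gene = GeneModel("g", "c", "+", [(0, 12)])
        rec = seqio.extract_cds_and_translate(genome, gene)
        assert "*" in rec.residues
        assert rec.flags["internal_stop"]

    def test_phase_error_flagged_not_raised(self):
        genome = [SequenceRecord("c", "ATGGCTTA")]
        gene = GeneModel("g", "c", "+", [(0, 8)])
        rec = seqio.extract_cds_and_translate(genome, gene)
        assert rec.flags["phase_error"]

    def test_two_exon_330bp_gene_gives_90aa_protein(self):
        """A 330-bp gene of two exons split by a 57-bp intron encodes 90 aa."""
        planted = synth.gen_mat11_13_gene(seed=7)
        gene_span = planted.gene.end - planted.gene.start
        assert gene_span == 330
        assert planted.gene.cds_length == 273  # includes the stop codon
        rec = seqio.extract_cds_and_translate({planted.contig.id: planted.contig}, planted.gene)
        assert len(rec.residues) == 90
        assert rec.residues == planted.protein


class TestSixFrame:
    def test_forward_frame1(self):
        frames = seqio.six_frame_translate(SequenceRecord("c", "ATGGCT"))
        assert frames[0].protein == "MA"

    def test_reverse_frame1_of_revcomp(self):
        frames = seqio.six_frame_translate(SequenceRecord("c", "AGCCAT"))
        rev = [f for f in frames if f.frame == -1][0]
        assert rev.protein == "MA"

    def test_frame_length_law(self, rng):
        contig = SequenceRecord("c", synth.random_dna(101, rng))
        for f in seqio.six_frame_translate(contig):
            offset = abs(f.frame) - 1
            assert len(f.protein) == (101 - offset) // 3

    def test_coordinate_mapping_round_trip(self, rng):
        dna = synth.random_dna(99, rng)
        contig = SequenceRecord("c", dna)
        for f in seqio.six_frame_translate(contig):
            s, e = f.protein_to_contig(2, 5)
            assert 0 <= s < e <= len(dna)
            sub = dna[s:e]
            if f.frame < 0:
                sub = seqio.revcomp(sub)
            assert seqio.translate_dna(sub) == f.protein[2:5]
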