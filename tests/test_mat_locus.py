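import numpy as np
import pytest

from _oracles import brute_force_pairs
from pheromat import synth
from pheromat.mat_locus import (
    LocusGene,
    RepeatPair,
    classify_thallism,
    detect_repeat_pairs,
    locate_mat_locus,
)
from pheromat.seqio import revcomp


class TestDetectRepeatPairs:
    def _window(self, rng, repeat_len=120, inverted=False, gap=400):
        rep = synth.random_dna(repeat_len, rng)
        second = revcomp(rep) if inverted else rep
        return (
            synth.random_dna(300, rng) + rep + synth.random_dna(gap, rng)
            + second + synth.random_dna(300, rng),
            rep,
        )

    def test_planted_inverted_pair(self, rng):
        dna, _ = self._window(rng, 250, inverted=True, gap=3000)
        pairs = detect_repeat_pairs(dna, min_len=100)
        assert len(pairs) == 1
        assert pairs[0].orientation == "inverted"
        # maximal extension may add a base or two of chance flank identity
        assert 250 <= pairs[0].length_bp <= 256
        assert pairs[0].seq_a_interval[0] <= 300 < pairs[0].seq_a_interval[1]

    def test_planted_direct_pair(self, rng):
        dna, _ = self._window(rng, 250, inverted=False, gap=3000)
        pairs = detect_repeat_pairs(dna, min_len=100)
        assert len(pairs) == 1
        assert pairs[0].orientation == "direct"
        assert 250 <= pairs[0].length_bp <= 256
        assert pairs[0].seq_a_interval[0] <= 300 < pairs[0].seq_a_interval[1]

    def test_random_window_has_no_pairs(self, rng):
        assert detect_repeat_pairs(synth.random_dna(10000, rng), min_len=100) == []

    def test_intervals_cover_planted_copies(self, rng):
        dna, rep = self._window(rng, 150, inverted=False)
        p = detect_repeat_pairs(dna, min_len=100)[0]
        a, b = p.seq_a_interval, p.seq_b_interval
        assert dna[a[0] : a[1]] == dna[b[0] : b[1]]

    @pytest.mark.parametrize("inverted", [False, True])
    def test_brute_force_oracle(self, inverted):
        """Seed-and-extend detection equals all-pairs comparison on small windows."""
        rng = np.random.default_rng(5)
        for trial in range(3):
            dna, _ = self._window(rng, 40, inverted=inverted, gap=150)
            got = {
                (p.seq_a_interval[0], p.seq_b_interval[0], p.length_bp, p.orientation)
                for p in detect_repeat_pairs(dna, min_len=30)
            }
            expected = brute_force_pairs(dna, min_len=30)
            assert got == expected

    def test_fuzzy_identity_not_supported(self):
        with pytest.raises(NotImplementedError):
            detect_repeat_pairs("ACGT" * 100, identity_min=0.9)


def lg(name, status, contig="c1"):
    return LocusGene(name, status, contig, (0, 10) if status != "absent" else None)


def rp(orientation):
    return RepeatPair((100, 350), (3000, 3250), 250, orientation)


class TestClassifyThallism:
    def test_botrytis_mat11_idiomorph(self):
        # MAT1-1-1 and MAT1-1-5 intact plus an opposite-idiomorph fragment
        call = classify_thallism(
            [lg("MAT1-1-1", "intact"), lg("MAT1-1-5", "intact"), lg("MAT1-2-1", "fragment")]
        )
        assert call.strategy == "heterothallic_MAT1_1"

    def test_mat12_idiomorph(self):
        call = classify_thallism([lg("MAT1-2-1", "intact"), lg("MAT1-2-10", "intact")])
        assert call.strategy == "heterothallic_MAT1_2"

    def test_switching_inversion_signature(self):
        genes = [
            lg("MAT1-1-5", "intact"), lg("MAT1-2-1", "intact"), lg("MAT1-2-10", "intact"),
            lg("MAT1-1-1", "fragment"), lg("MAT1-1-1", "fragment"),
        ]
        call = classify_thallism(genes, [rp("inverted")])
        assert call.strategy == "switching_inversion"

    def test_switching_deletion_signature(self):
        genes = [
            lg("MAT1-1-1", "intact"), lg("MAT1-1-5", "intact"),
            lg("MAT1-2-1", "intact"), lg("MAT1-2-10", "intact"),
        ]
        assert classify_thallism(genes, [rp("direct")]).strategy == "switching_deletion"

    def test_lachnellula_hmg_only(self):
        assert classify_thallism([lg("MAT1-1-3", "intact")]).strategy == "lachnellula_HMG_only"

    def test_lachnellula_needs_no_mat111_anywhere(self):
        call = classify_thallism([lg("MAT1-1-3", "intact"), lg("MAT1-1-1", "fragment")])
        assert call.strategy != "lachnellula_HMG_only"

    def test_fused_locus_is_primary_homothallic(self):
        genes = [
            lg("MAT1-1-1", "intact"), lg("MAT1-1-3", "intact"), lg("MAT1-2-1", "intact"),
        ]
        assert classify_thallism(genes).strategy == "primary_homothallic"

    def test_split_idiomorphs_mixed_culture(self):
        genes = [
            lg("MAT1-1-1", "intact", "c1"), lg("MAT1-1-3", "intact", "c1"),
            lg("MAT1-2-1", "intact", "c2"),
        ]
        assert classify_thallism(genes).strategy == "possible_mixed_culture"

    def test_truncated_principal_undetermined(self):
        genes = [lg("MAT1-1-1", "truncated_5prime"), lg("MAT1-2-1", "intact")]
        assert classify_thallism(genes).strategy == "undetermined"

    def test_single_idiomorph_with_repeats_is_ambiguous(self):
        genes = [
            lg("MAT1-1-5", "intact"),
            lg("MAT1-1-1", "fragment"), lg("MAT1-1-1", "fragment"),
        ]
        assert classify_thallism(genes, [rp("inverted")]).strategy == "undetermined"

    def test_every_call_has_evidence(self):
        for genes in (
            [lg("MAT1-1-1", "intact")],
            [lg("MAT1-2-1", "intact")],
            [],
        ):
            call = classify_thallism(genes)
            assert call.evidence


class TestArchitectureFixtures:
    """Every named synthetic locus architecture classifies to its intended strategy."""

    @pytest.mark.parametrize("name", synth.MAT_ARCHITECTURES)
    def test_architecture_round_trip(self, name, references):
        arch = synth.gen_mat_architecture(name, seed=23)
        locus = locate_mat_locus(arch.contigs, references)
        pairs = []
        if locus.window is not None:
            cmap = {c.id: c for c in arch.contigs}
            ws, we = locus.window[1]
            pairs = detect_repeat_pairs(cmap[locus.window[0]].residues[ws:we])
        call = classify_thallism(locus.genes, pairs)
        assert call.strategy == synth.ARCHITECTURE_STRATEGY[name]

    def test_truncation_side_detected(self, references):
        arch = synth.gen_mat_architecture("truncated_undetermined", seed=23)
        locus = locate_mat_locus(arch.contigs, references)
        trunc = [g for g in locus.genes if g.name == "MAT1-1-1" and g.status != "absent"]
        assert any(g.status == "truncated_5prime" for g in trunc)
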