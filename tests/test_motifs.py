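import re

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pheromat import motifs
from pheromat.motifs import (
    find_gy_motif,
    find_kex_sites,
    find_ste13_sites,
    hydropathy_segments,
    st_fraction,
    terminal_caax_class,
)

AA = "ACDEFGHIKLMNPQRSTVWY"
protein_st = st.text(alphabet=AA, min_size=0, max_size=60)


class TestTerminalBox:
    @pytest.mark.parametrize(
        "tail,expected",
        [
            ("CTVM", "CPAX"),  # T polar at position 2: the commonest box
            ("CVVM", "CAAX"),
            ("CIVM", "CAAX"),
            ("CTIL", "CPAX"),
            ("CSIM", "CPAX"),
            ("CSVM", "CPAX"),
            ("ACDE", "none"),  # no C at -4
            ("CGVM", "none"),  # G in neither class
            ("CVGM", "none"),  # position 3 must be aliphatic
        ],
    )
    def test_observed_boxes(self, tail, expected):
        assert terminal_caax_class("MSSTTAA" + tail) == expected

    def test_too_short_returns_none(self):
        assert terminal_caax_class("CVM") == "none"

    @given(prefix=protein_st, tail=st.text(alphabet=AA, min_size=4, max_size=4))
    @settings(max_examples=200, derandomize=True)
    def test_prefix_invariance(self, prefix, tail):
        """The verdict is a pure function of the final four residues."""
        assert terminal_caax_class("M" + prefix + tail) == terminal_caax_class("XXXX" + tail)


class TestKexSites:
    def test_single_site(self):
        hits = find_kex_sites("WCGRPGQPCKR")
        assert [(h.start, h.end) for h in hits] == [(9, 11)]

    def test_overlapping_sites(self):
        hits = find_kex_sites("AKKRA")
        assert [(h.start, h.end) for h in hits] == [(1, 3), (2, 4)]

    def test_no_sites(self):
        assert find_kex_sites("ACDEFG") == []

    @given(protein=protein_st)
    @settings(max_examples=300, derandomize=True)
    def test_regex_oracle_equivalence(self, protein):
        expected = sorted(
            m.start() for m in re.finditer(r"(?=(KR|RR|KK))", protein)
        )
        assert [h.start for h in find_kex_sites(protein)] == expected


class TestSte13Sites:
    def test_xaxa_run_is_one_hit(self):
        hits = find_ste13_sites("DAEA")
        assert [(h.start, h.end) for h in hits] == [(0, 4)]

    def test_singleton_xp(self):
        hits = find_ste13_sites("MSEPKW")
        assert [(h.start, h.end) for h in hits] == [(2, 4)]

    def test_no_sites(self):
        assert find_ste13_sites("KKKK") == []

    def test_long_run_extends(self):
        hits = find_ste13_sites("WDAEPDAW")
        assert (1, 7) in [(h.start, h.end) for h in hits]


class TestStFraction:
    @pytest.mark.parametrize(
        "protein,frac",
        [("SSTTSSTTSS", 1.0), ("AAAAAAAAAA", 0.0), ("MSTSTAAAAT", 0.5), ("MSTSTAAAST", 0.6)],
    )
    def test_hand_counts(self, protein, frac):
        assert st_fraction(protein, 10) == pytest.approx(frac)

    def test_window_clips_to_length(self):
        assert st_fraction("ST", 20) == 1.0

    def test_empty_protein_raises(self):
        with pytest.raises(ValueError):
            st_fraction("", 10)

    @given(protein=st.text(alphabet=AA, min_size=1, max_size=40))
    @settings(max_examples=200, derandomize=True)
    def test_bounds_and_monotonicity(self, protein):
        f = st_fraction(protein, 20)
        assert 0.0 <= f <= 1.0
        # replacing any prefix residue by S never lowers the fraction
        i = min(len(protein) - 1, 5)
        swapped = protein[:i] + "S" + protein[i + 1 :]
        assert st_fraction(swapped, 20) >= f


class TestGyMotif:
    def test_gy_in_tail_window(self):
        hit = find_gy_motif("MSSTTAAAAAAGYAACTVM", tail_window=15)
        assert hit is not None and hit.start == 11

    def test_no_gy(self):
        assert find_gy_motif("MSSTTAAAAAAAAACTVM", tail_window=15) is None

    def test_gy_outside_window_ignored(self):
        protein = "GY" + "A" * 54 + "CTVM"
        assert find_gy_motif(protein, tail_window=15) is None

    def test_last_gy_reported(self):
        protein = "MGYAAAGYAACTVM"
        hit = find_gy_motif(protein, tail_window=15)
        assert hit.start == 6


class TestHydropathy:
    def test_seven_tm_construct(self):
        protein = "".join("L" * 21 + "S" * 10 for _ in range(7))
        assert len(hydropathy_segments(protein)) == 7

    def test_poly_ser_has_no_segment(self):
        assert hydropathy_segments("S" * 120) == []

    def test_short_protein_empty(self):
        assert hydropathy_segments("LLLL") == []

    def test_signal_like_prefix(self):
        protein = "MKFLSLLALAAVVSA" + "DENQKR" * 10
        sig = motifs.find_signal_region(protein)
        assert sig is not None and sig.start <= 3

    def test_hydrophilic_tail_invariance(self):
        """Appending hydrophilic residues never changes the segment count."""
        core = "".join("L" * 21 + "S" * 12 for _ in range(3))
        base = len(hydropathy_segments(core))
        assert base == 3
        for tail_len in (5, 40, 100):
            assert len(hydropathy_segments(core + "D" * tail_len)) == base

    def test_window_must_be_odd(self):
        with pytest.raises(ValueError):
            hydropathy_segments("L" * 50, window=10)
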