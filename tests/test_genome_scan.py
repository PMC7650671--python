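"""Scanner unit and property tests: arms, filters, oracle agreement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from palinsig.genome_scan import (
    CoreMotif,
    PalindromicLocus,
    ReferenceSequence,
    is_arm_homopolymer,
    max_arm_length,
    passes_repeat_filter,
    reverse_complement,
    scan_core_motif,
    scan_variant_window,
)

TGAACA = CoreMotif("TGAACA")

dna = st.text(alphabet="ACGT", min_size=1, max_size=200)


def brute_force_scan(seq: ReferenceSequence, core: CoreMotif,
                     min_arm: int, max_arm: int | None):
    """Quadratic oracle: try every position in both orientations, extend
    arms base by base with direct slice comparison."""
    up = seq.bases.upper()
    L = len(core)
    hits = {}
    for pattern, strand in ((core.sequence, "+"), (reverse_complement(core.sequence), "-")):
        for start in range(0, len(up) - L + 1):
            if up[start : start + L] != pattern:
                continue
            k = 0
            while True:
                left = up[start - k - 1 : start]  # careful with negative slice
                if start - k - 1 < 0 or start + L + k + 1 > len(up):
                    break
                l_base = up[start - k - 1]
                r_base = up[start + L + k]
                if "N" in (l_base, r_base) or l_base != reverse_complement(r_base):
                    break
                k += 1
            if k >= min_arm and (max_arm is None or k <= max_arm):
                left_arm = up[start - k : start]
                right_arm = up[start + L : start + L + k]
                if len(set(left_arm)) == 1 or len(set(right_arm)) == 1:
                    continue  # homopolymer filter
                hits.setdefault((start, L), (start, k, strand))
    return sorted(hits.values())


class TestReverseComplement:
    @pytest.mark.parametrize(
        "seq,expected",
        [("TGAACA", "TGTTCA"), ("AGATCA", "TGATCT"), ("acgtN", "Nacgt"), ("A", "T")],
    )
    def test_examples(self, seq, expected):
        assert reverse_complement(seq) == expected

    def test_rejects_non_dna_with_position(self):
        with pytest.raises(ValueError, match="position 2"):
            reverse_complement("ACXGT")

    @given(dna)
    @settings(max_examples=200, deadline=None)
    def test_involution(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq


class TestMaxArmLength:
    def test_derived_arm_nine(self):
        # flanking A/A pair cannot pair, so extension stops at k = 9
        seq = ReferenceSequence("t", "AAAA" + "CATTGGCGA" + "TGAACA" + "TCGCCAATG" + "AAAA")
        assert max_arm_length(seq, 13, 6) == 9

    def test_t_cannot_pair_with_t(self):
        assert max_arm_length(ReferenceSequence("t", "TTTTTGAACATTTT"), 4, 6) == 0

    def test_no_left_flank_at_position_zero(self):
        assert max_arm_length(ReferenceSequence("t", "TGAACAGGGGGG"), 0, 6) == 0

    def test_bounded_by_right_end(self):
        # perfect palindrome but nothing beyond the right arm
        seq = ReferenceSequence("t", "G" + "CAT" + "TGAACA" + "ATG")
        assert max_arm_length(seq, 4, 6) == 3

    def test_n_breaks_extension(self):
        seq = ReferenceSequence("t", "GNAT" + "TGAACA" + "ATNC")
        assert max_arm_length(seq, 4, 6) == 2

    def test_case_insensitive(self):
        seq = ReferenceSequence("t", "g" + "cat" + "TGAACA" + "atg".upper())
        assert max_arm_length(seq, 4, 6) == 3

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError, match="outside sequence"):
            max_arm_length(ReferenceSequence("t", "ACGT"), 2, 6)


class TestScanCoreMotif:
    def test_recovers_only_implant(self):
        arm = "CATTGGCGA"
        body = ("GG" * 10 + arm + "TGAACA" + reverse_complement(arm)
                + "GG" * 10 + "TGAACA" + "GG" * 10)
        seq = ReferenceSequence("s", body)
        loci = scan_core_motif(seq, TGAACA, min_arm=9, max_arm=11)
        assert [(l.core_start, l.arm_length) for l in loci] == [(29, 9)]

    def test_strand_symmetry(self):
        arm = "CATTGGCGA"
        body = "GGA" * 8 + arm + "TGAACA" + reverse_complement(arm) + "CTT" * 8
        seq = ReferenceSequence("s", body)
        fwd = scan_core_motif(seq, TGAACA, min_arm=9, max_arm=None)
        mirrored = ReferenceSequence("s", reverse_complement(body))
        rev = scan_core_motif(mirrored, TGAACA, min_arm=9, max_arm=None)
        assert len(fwd) == len(rev) == 1
        # mirrored coordinate of the core interval
        assert rev[0].core_start == len(body) - fwd[0].core_end
        assert rev[0].arm_length == fwd[0].arm_length
        assert {fwd[0].strand_label, rev[0].strand_label} == {"+", "-"}

    def test_maximality_of_reported_arms(self):
        rng = np.random.default_rng(0)
        bases = "".join(rng.choice(list("ACGT"), 4000))
        seq = ReferenceSequence("r", bases)
        for locus in scan_core_motif(seq, TGAACA, min_arm=1, max_arm=None):
            k = locus.arm_length
            s, L = locus.core_start, len(locus.core)
            lo, hi = s - k - 1, s + L + k
            extendable = (
                lo >= 0 and hi < len(bases)
                and bases[lo].upper() == reverse_complement(bases[hi].upper())
            )
            assert not extendable

    def test_mutable_positions_three_apart(self):
        arm = "CATTGGCGA"
        seq = ReferenceSequence("s", "GG" + arm + "TGAACA" + reverse_complement(arm) + "GG")
        (locus,) = scan_core_motif(seq, TGAACA, min_arm=9, max_arm=None)
        a, b = locus.mutable_positions
        assert b - a == 3

    @pytest.mark.parametrize("seed", range(25))
    def test_agrees_with_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        bases = "".join(rng.choice(list("ACGTN"), p=[0.24, 0.24, 0.24, 0.24, 0.04],
                                   size=rng.integers(200, 3000)))
        if set(bases) == {"N"}:
            bases = "ACGT"
        seq = ReferenceSequence("r", bases)
        got = [(l.core_start, l.arm_length, l.strand_label)
               for l in scan_core_motif(seq, TGAACA, min_arm=1, max_arm=None)]
        assert got == brute_force_scan(seq, TGAACA, 1, None)


class TestFilters:
    def _locus(self, arm_len=9, masked=0.0):
        return PalindromicLocus("c", 20, TGAACA, arm_len, "+", masked)

    def test_homopolymer_arms_detected(self):
        seq = ReferenceSequence("c", "G" * 11 + "A" * 9 + "TGAACA" + "T" * 9 + "G" * 11)
        assert is_arm_homopolymer(PalindromicLocus("c", 20, TGAACA, 9, "+"), seq)

    def test_mixed_arms_pass(self):
        arm = "CATTGGCGA"
        seq = ReferenceSequence("c", "G" * 20 + arm + "TGAACA" + reverse_complement(arm) + "G" * 5)
        assert not is_arm_homopolymer(PalindromicLocus("c", 29, TGAACA, 9, "+"), seq)

    def test_zero_arm_is_vacuously_not_homopolymer(self):
        seq = ReferenceSequence("c", "G" * 20 + "TGAACA" + "G" * 20)
        assert not is_arm_homopolymer(PalindromicLocus("c", 20, TGAACA, 0, "+"), seq)

    def test_repeat_filter_thresholds(self):
        assert passes_repeat_filter(self._locus(masked=0.0), 0.0)
        assert not passes_repeat_filter(self._locus(masked=1 / 24), 0.0)
        assert passes_repeat_filter(self._locus(masked=1 / 24), 0.5)

    def test_scan_drops_homopolymer_armed_locus(self):
        seq = ReferenceSequence("c", "G" * 11 + "A" * 9 + "TGAACA" + "T" * 9 + "G" * 11)
        assert scan_core_motif(seq, TGAACA, min_arm=9, max_arm=None) == []
        kept = scan_core_motif(seq, TGAACA, min_arm=9, max_arm=None,
                               homopolymer_filter=False)
        assert [l.arm_length for l in kept] == [9]

    def test_masked_fraction_measured_over_arms_and_core(self):
        arm = "CATTGGCGA"
        body = "GG" + arm.lower()[:1] + arm[1:] + "TGAACA" + reverse_complement(arm) + "GG"
        seq = ReferenceSequence("c", body)
        (locus,) = scan_core_motif(seq, TGAACA, min_arm=9, max_arm=None)
        assert locus.masked_fraction == pytest.approx(1 / 24)


class TestVariantWindow:
    @staticmethod
    def _window_with_construct(arm_len=8, seed=5):
        """Random 61-mer with an arm+TGAACA+revcomp(arm) construct whose
        variant base (core offset 1) sits at window offset 30."""
        rng = np.random.default_rng(seed)
        arm = "".join(rng.choice(list("ACGT"), arm_len))
        while len(set(arm)) == 1:
            arm = "".join(rng.choice(list("ACGT"), arm_len))
        construct = arm + "TGAACA" + reverse_complement(arm)
        core_start = 30 - 1  # variant at core offset 1
        left_pad = core_start - arm_len
        right_pad = 61 - (left_pad + len(construct))
        # pad with C on both sides: C cannot pair with C, so the pads
        # neither extend the planted arm nor form arms of their own
        window = ("C" * left_pad + construct + "C" * right_pad)
        return window, core_start

    def test_implanted_construct_reported(self):
        window, core_start = self._window_with_construct(arm_len=8)
        got = scan_variant_window(window, variant_offset=30, min_arm=8)
        assert any(c.core_start_in_window == core_start and c.core_len == 6
                   and c.arm_length >= 8 for c in got)

    def test_homopolymer_window_is_empty(self):
        assert scan_variant_window("A" * 61, variant_offset=30) == []

    def test_arms_of_seven_rejected(self):
        window, _ = self._window_with_construct(arm_len=7)
        got = scan_variant_window(window, variant_offset=30, min_arm=8)
        assert got == []

    def test_short_window_warns_and_returns_empty(self, caplog):
        with caplog.at_level("WARNING"):
            assert scan_variant_window("ACGTACGTAC", variant_offset=5) == []
        assert any("too short" in r.message for r in caplog.records)

    def test_all_candidates_contain_variant(self):
        window, _ = self._window_with_construct(arm_len=9)
        for c in scan_variant_window(window, variant_offset=30, min_arm=8):
            assert c.core_start_in_window <= 30 < c.core_start_in_window + c.core_len
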