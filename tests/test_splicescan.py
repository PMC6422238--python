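"""Splice-site calls and the terminal-exon rescue scan."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from lossscan.genemodels import NucSequence
from lossscan.splicescan import (
    CrdCterminalProfile,
    RescueParams,
    call_acceptor,
    call_donor,
    rescue_terminal_exon,
)
from lossscan.synthdata import ACCEPTOR_GG, LocusSpec, consensus_profile, make_locus


class TestDonor:
    @pytest.mark.parametrize(
        "intron_start, canonical, ambiguous",
        [("GT", True, False), ("AT", False, False), ("GN", False, True), ("GC", False, False)],
    )
    def test_dinucleotide_rules(self, intron_start, canonical, ambiguous):
        locus = NucSequence("L", "AAA" + intron_start + "AAA")
        call = call_donor(locus, 3)
        assert call.canonical is canonical
        assert call.ambiguous is ambiguous
        assert call.dinucleotide == intron_start

    def test_out_of_range(self):
        with pytest.raises(IndexError):
            call_donor(NucSequence("L", "ACGT"), 3)


class TestAcceptor:
    def test_saturated_tract(self):
        locus = NucSequence("L", "T" * 20 + "AG" + "CCC")
        call = call_acceptor(locus, 22, ppt_window=20)
        assert call.canonical and call.ppt_score == 1.0

    def test_gg_not_canonical(self):
        locus = NucSequence("L", "T" * 20 + "GG" + "CCC")
        call = call_acceptor(locus, 22, ppt_window=20)
        assert not call.canonical
        assert call.dinucleotide == "GG"

    def test_ppt_direct_count(self):
        # 13 pyrimidines in a 20-base window
        window = "CT" * 6 + "T" + "A" * 7
        assert sum(b in "CT" for b in window) == 13
        locus = NucSequence("L", window + "AG" + "CCC")
        call = call_acceptor(locus, 22, ppt_window=20)
        assert call.ppt_score == pytest.approx(0.65)

    def test_out_of_range(self):
        with pytest.raises(IndexError):
            call_acceptor(NucSequence("L", "A" * 10), 8, ppt_window=20)

    @given(st.integers(min_value=0, max_value=20))
    def test_ppt_monotone_in_pyrimidines(self, k):
        # replacing A's by T's from the left never lowers the score
        window = "T" * k + "A" * (20 - k)
        locus = NucSequence("L", window + "AG" + "C" * 3)
        score_k = call_acceptor(locus, 22, ppt_window=20).ppt_score
        assert score_k == pytest.approx(k / 20)
        if k < 20:
            more = "T" * (k + 1) + "A" * (19 - k)
            locus2 = NucSequence("L", more + "AG" + "C" * 3)
            assert call_acceptor(locus2, 22, ppt_window=20).ppt_score >= score_k


def _flat(n):
    # AG-free filler so candidate positions are fully controlled
    return ("ACC" * (n // 3 + 1))[:n]


class TestRescue:
    def test_decoy_ranks_below_true_exon_hand_scored(self):
        """A pyrimidine-poor, zero-profile decoy acceptor upstream of the true
        exon must rank second; scores checked against the weight formula."""
        profile = CrdCterminalProfile(features=((0, "Q"), (1, "P"), (2, "D")))
        decoy_orf = "CAACCAGCT" * 12  # QPA...: matches Q,P but not D at offset 2
        true_orf = "CAACCAGAT" + "GCT" * 40  # QPD then open frame
        seq = (
            _flat(30)
            + "AAAAAAAAAAAAAAAAAAAA" + "AG" + decoy_orf  # decoy: ppt 0
            + _flat(9)
            + "TTTTTTTTTTTTTTTTTTTT" + "AG" + true_orf
            + _flat(30)
        )
        locus = NucSequence("L", seq)
        decoy_pos = 30 + 22
        true_pos = decoy_pos + len(decoy_orf) + 9 + 22
        params = RescueParams(min_codons=30)
        cands = rescue_terminal_exon(locus, 30, 0, profile, params)
        by_pos = {c.acceptor_pos: c for c in cands}
        t, d = by_pos[true_pos], by_pos[decoy_pos]
        # hand-computed: true = 1.0*1.0 + 1.0*(3/3) + 0.5*1; decoy = 0 + 2/3 + 0.5
        assert t.total_score == pytest.approx(2.5)
        assert d.total_score == pytest.approx(0.0 + 2 / 3 + 0.5)
        assert cands[0].acceptor_pos == true_pos
        assert cands.index(d) > 0

    def test_implanted_exon_is_top_candidate(self, functional_locus, default_profile):
        spec, locus, model, truth = functional_locus
        cands = rescue_terminal_exon(
            locus, truth.donor_pos, truth.frame, default_profile
        )
        assert cands[0].acceptor_pos == truth.acceptor_offset
        assert cands[0].profile_matches == len(default_profile)

    def test_mutated_acceptor_absent_from_candidates(self):
        spec = LocusSpec(seed=11, mutations=(ACCEPTOR_GG,))
        locus, model, truth = make_locus(spec)
        exon7_start = model.exons[-1].start
        cands = rescue_terminal_exon(
            locus, truth.donor_pos, truth.frame, consensus_profile(spec)
        )
        assert exon7_start not in [c.acceptor_pos for c in cands]

    def test_empty_span_returns_empty_list(self):
        locus = NucSequence("L", "A" * 100)
        profile = CrdCterminalProfile(features=((0, "Q"),))
        assert rescue_terminal_exon(locus, 100, 0, profile) == []

    @given(st.text(alphabet="ACGT", min_size=80, max_size=200))
    def test_every_candidate_preceded_by_ag(self, bases):
        locus = NucSequence("L", bases)
        profile = CrdCterminalProfile(features=((0, "ACDEFGHIKLMNPQRSTVWY"),))
        for c in rescue_terminal_exon(locus, 0, 0, profile, RescueParams(min_codons=5)):
            assert locus.residues[c.acceptor_pos - 2 : c.acceptor_pos] == "AG"

    def test_invariant_to_sequence_beyond_span(self, default_profile):
        spec = LocusSpec(seed=3)
        locus, model, truth = make_locus(spec)
        params = RescueParams(span=150, min_codons=5)
        before = rescue_terminal_exon(locus, truth.donor_pos, truth.frame, default_profile, params)
        # the candidate set and tract scores depend only on sequence within the
        # span (ORF translation deliberately reads past it, so ranking may not)
        cut = truth.donor_pos + 150
        mutated = NucSequence(locus.id, locus.residues[:cut] + "A" * (len(locus) - cut))
        after = rescue_terminal_exon(mutated, truth.donor_pos, truth.frame, default_profile, params)
        assert {c.acceptor_pos for c in after} == {c.acceptor_pos for c in before}
        ppt_before = {c.acceptor_pos: c.ppt_score for c in before}
        for c in after:
            assert c.ppt_score == ppt_before[c.acceptor_pos]
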