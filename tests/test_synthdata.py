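"""Generator determinism, implanted ground truth and recovery properties."""

import numpy as np
import pytest

from lossscan.crdclass import FunctionalStatus
from lossscan.glycanarray import EpitopeClass, rank_array
from lossscan.junctions import UNSPLICED, select_terminal_exon
from lossscan.splicescan import call_acceptor, call_donor, rescue_terminal_exon
from lossscan.synthdata import (
    ABSENT,
    ACCEPTOR_GG,
    DONOR_AT,
    LIVER_RESTRICTED,
    SPLEEN_DOMINANT,
    BACKGROUND_TPM,
    LocusSpec,
    ReceptorProfile,
    bovine_like_profile,
    consensus_profile,
    make_locus,
    simulate_array,
    simulate_expression,
    simulate_junctions,
)


class TestMakeLocus:
    def test_deterministic(self):
        spec = LocusSpec(seed=21, mutations=(ACCEPTOR_GG,))
        l1, m1, t1 = make_locus(spec)
        l2, m2, t2 = make_locus(spec)
        assert l1.residues == l2.residues
        assert m1 == m2 and t1 == t2

    def test_acceptor_gg_by_construction(self):
        locus, model, truth = make_locus(LocusSpec(seed=4, mutations=(ACCEPTOR_GG,)))
        call = call_acceptor(locus, model.exons[-1].start)
        assert not call.canonical and call.dinucleotide == "GG"
        assert truth.expected_chosen == UNSPLICED

    def test_donor_at_by_construction(self):
        locus, model, truth = make_locus(LocusSpec(seed=4, mutations=(DONOR_AT,)))
        call = call_donor(locus, truth.donor_pos)
        assert not call.canonical and call.dinucleotide == "AT"

    def test_functional_locus_canonical_sites_and_tract(self):
        locus, model, truth = make_locus(LocusSpec(seed=4))
        for a, b in zip(model.exons, model.exons[1:]):
            assert call_donor(locus, a.end).canonical
            acc = call_acceptor(locus, b.start)
            assert acc.canonical and acc.ppt_score >= 0.7

    def test_motif_and_cysteines_implanted(self):
        spec = LocusSpec(seed=9, motif="QPD")
        locus, model, truth = make_locus(spec)
        crd = truth.crd_protein.residues
        assert crd[truth.motif_offset : truth.motif_offset + 3] == "QPD"
        assert crd.count("C") >= 4

    def test_motif_mutation_changes_tripeptide_only(self):
        base = make_locus(LocusSpec(seed=9))[2].crd_protein.residues
        swapped = make_locus(LocusSpec(seed=9, mutations=("MOTIF:QSD",)))[2]
        crd = swapped.crd_protein.residues
        assert crd[swapped.motif_offset : swapped.motif_offset + 3] == "QSD"
        diffs = [i for i, (x, y) in enumerate(zip(base, crd)) if x != y]
        assert set(diffs) <= {swapped.motif_offset + 1}

    def test_impossible_spec_rejected(self):
        with pytest.raises(ValueError):
            make_locus(LocusSpec(exon_lengths=(120, 81, 72, 150, 141, 131, 121),
                                 intron_lengths=(400, 350, 300, 320, 280, 10)))
        with pytest.raises(ValueError):
            make_locus(LocusSpec(exon_lengths=(300, 81, 72, 150, 141, 132, 12),
                                 intron_lengths=(400, 350, 300, 320, 280, 300)))

    def test_rescue_recovery_over_100_seeds_without_decoy(self):
        """With no implanted decoy, the rescue scan's top candidate equals the
        implanted acceptor in 100% of seeded loci."""
        profile = consensus_profile(LocusSpec())
        hits = 0
        for seed in range(100):
            locus, model, truth = make_locus(LocusSpec(seed=seed, decoy_exon_x=False))
            cands = rescue_terminal_exon(locus, truth.donor_pos, truth.frame, profile)
            hits += cands[0].acceptor_pos == truth.acceptor_offset
        assert hits == 100


class TestSimulateJunctions:
    def test_functional_locus_supports_exon7(self):
        locus, model, truth = make_locus(LocusSpec(seed=2))
        candidates = {"exon7": truth.acceptor_offset, "exonX": truth.decoy_acceptor_pos}
        for seed in range(50):
            records = simulate_junctions(model, truth, depth=20, seed=seed)
            call = select_terminal_exon(records, candidates, min_reads=2)
            assert call.chosen == "exon7"

    def test_unspliced_truth_has_no_final_junction_reads(self):
        locus, model, truth = make_locus(LocusSpec(seed=2, mutations=(ACCEPTOR_GG,)))
        records = simulate_junctions(model, truth, depth=20, seed=1)
        final_acceptor = model.exons[-1].start
        assert all(r.acceptor_pos != final_acceptor for r in records)
        assert all(r.reads <= 1 for r in records)

    def test_depth_zero_is_empty(self):
        locus, model, truth = make_locus(LocusSpec(seed=2))
        assert simulate_junctions(model, truth, depth=0, seed=1) == []

    def test_deterministic(self):
        locus, model, truth = make_locus(LocusSpec(seed=2))
        a = simulate_junctions(model, truth, depth=15, seed=9)
        b = simulate_junctions(model, truth, depth=15, seed=9)
        assert a == b


class TestSimulateArray:
    def test_lewis_preferring_profile_tops_ranking(self):
        spots = simulate_array(bovine_like_profile(), seed=0)
        top10 = rank_array(spots, top_n=10)
        assert all(s.epitope is EpitopeClass.LEWIS for s in top10)

    def test_all_other_panel_stays_other(self):
        glycans = ("Mana1-2Man-Sp8", "Glcb1-4Glc-Sp8", "GlcNAcb1-4GlcNAc-Sp8")
        spots = simulate_array(bovine_like_profile(), glycans=glycans, seed=3)
        assert all(s.epitope is EpitopeClass.OTHER for s in spots)

    def test_deterministic(self):
        a = simulate_array(bovine_like_profile(), seed=5)
        b = simulate_array(bovine_like_profile(), seed=5)
        assert [s.replicates for s in a] == [s.replicates for s in b]

    def test_replicates_non_negative_and_six(self):
        spots = simulate_array(
            ReceptorProfile(class_signal={EpitopeClass.LEWIS: 100.0}, noise_sd=500.0),
            seed=1,
        )
        for s in spots:
            assert len(s.replicates) == 6
            assert min(s.replicates) >= 0.0


class TestSimulateExpression:
    def test_liver_restricted_ratio_recomputed(self):
        table = simulate_expression(LIVER_RESTRICTED, seed=0)
        by = table.set_index("tissue")["abundance"]
        ratio = by["liver"] / by.drop("liver").max()
        assert ratio >= 1000

    def test_absent_below_background(self):
        table = simulate_expression(ABSENT, seed=0)
        assert (table["abundance"] < BACKGROUND_TPM).all()

    def test_spleen_dominant_argmax(self):
        table = simulate_expression(SPLEEN_DOMINANT, seed=0)
        assert table.loc[table["abundance"].idxmax(), "tissue"] == "spleen"

    def test_unknown_pattern_rejected(self):
        with pytest.raises(ValueError):
            simulate_expression("LUNG_ONLY", seed=0)
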