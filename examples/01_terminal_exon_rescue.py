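"""Rescue the true terminal exon of a receptor gene from a miscalled model.

Automated annotation sometimes splices a gene's last intron to a fortuitous
in-frame acceptor ("exon X") instead of the real terminal exon further along
the chromosome. We generate a synthetic seven-exon locus that contains both
the true exon and such a decoy, then let the rescue scan rank every candidate
acceptor downstream of the penultimate exon's donor site.
"""

from lossscan import LocusSpec, consensus_profile, make_locus, rescue_terminal_exon

spec = LocusSpec(seed=5)
locus, model, truth = make_locus(spec)
profile = consensus_profile(spec)

candidates = rescue_terminal_exon(locus, truth.donor_pos, truth.frame, profile)

print(f"scanned {len(candidates)} AG acceptors downstream of position {truth.donor_pos}")
print("top 3 candidates (score = tract + profile + frame):")
for c in candidates[:3]:
    tag = ""
    if c.acceptor_pos == truth.acceptor_offset:
        tag = "  <- implanted true exon"
    elif c.acceptor_pos == truth.decoy_acceptor_pos:
        tag = "  <- decoy 'exon X'"
    print(
        f"  pos {c.acceptor_pos}: ppt {c.ppt_score:.2f}, "
        f"profile {c.profile_matches}/{len(profile)}, orf {c.orf_len} codons, "
        f"total {c.total_score:.2f}{tag}"
    )

decoy = next(c for c in candidates if c.acceptor_pos == truth.decoy_acceptor_pos)
print(
    f"\nthe decoy at {decoy.acceptor_pos} is in-frame (orf {decoy.orf_len} codons) —"
    " exactly the trap that fools splice predictors — but its weak pyrimidine"
    f" tract ({decoy.ppt_score:.2f}) and absent protein features rank it below"
    " the true exon."
)
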