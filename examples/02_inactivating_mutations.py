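"""Call a gene's functional status from splice-site and binding-motif evidence.

A galactose-type C-type lectin needs a canonical GT..AG final intron, the
Gln-Pro-Asp (QPD) tripeptide at its principal Ca2+ site and an intact set of
conserved cysteines. We implant a human-like pair of defects — the final
acceptor mutated AG->GG plus the motif mutated QPD->QSD — and watch the
classifier count two independent defects.
"""

from lossscan import (
    ACCEPTOR_GG,
    LocusSpec,
    build_crd_report,
    call_acceptor,
    call_donor,
    make_locus,
)

for label, mutations in [("intact", ()), ("human-like", (ACCEPTOR_GG, "MOTIF:QSD"))]:
    spec = LocusSpec(seed=17, mutations=mutations)
    locus, model, truth = make_locus(spec)
    final_exon = model.exons[-1]
    acceptor = call_acceptor(locus, final_exon.start)
    donor = call_donor(locus, truth.donor_pos)
    report = build_crd_report(
        truth.crd_protein, truth.motif_offset, [acceptor], [donor], expected_cys=4
    )
    print(f"{label}:")
    print(f"  final acceptor: {acceptor.dinucleotide} (canonical={acceptor.canonical})")
    print(f"  motif tripeptide: {report.tripeptide} -> {report.motif.value}")
    print(f"  cysteines: {report.cys_count} (ok={report.cys_ok})")
    print(f"  status: {report.status.value}\n")

print(
    "the intact gene is FUNCTIONAL_GAL; with a dead splice site AND a dead"
    " binding site the status is PSEUDO_MULTIPLE — two independent reasons no"
    " functional receptor can be made."
)
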