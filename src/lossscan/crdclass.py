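"""Carbohydrate-recognition-domain (CRD) integrity checks and status calls.

C-type CRDs bind sugar through a Ca2+ ion coordinated by five conserved
residues; the tripeptide at the principal site determines specificity:
Glu-Pro-Asn (EPN) for mannose/GlcNAc binding, Gln-Pro-Asp (QPD) for
galactose/GalNAc binding. The central proline must adopt the cis
configuration, so any middle residue other than proline is disqualifying.
Conserved cysteines form the disulfides that hold the fold together, and the
neck that trimerizes the receptor shows a heptad repeat of hydrophobics.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

HYDROPHOBIC = frozenset("LIVMFA")


class MotifClass(enum.Enum):
    GAL = "GAL"  # Gln-Pro-Asp: galactose/GalNAc specificity
    MAN = "MAN"  # Glu-Pro-Asn: mannose/GlcNAc specificity
    INVALID = "INVALID"


class FunctionalStatus(enum.Enum):
    FUNCTIONAL_GAL = "FUNCTIONAL_GAL"
    FUNCTIONAL_MAN = "FUNCTIONAL_MAN"
    PSEUDO_SPLICE = "PSEUDO_SPLICE"
    PSEUDO_BINDING_SITE = "PSEUDO_BINDING_SITE"
    PSEUDO_MULTIPLE = "PSEUDO_MULTIPLE"
    INDETERMINATE = "INDETERMINATE"


@dataclass(frozen=True)
class CRDReport:
    """Combined evidence about one gene's CRD."""

    motif: MotifClass
    tripeptide: str
    cys_count: int
    cys_ok: bool
    status: FunctionalStatus
    heptad: float | None = None


def classify_binding_motif(tripeptide: str) -> MotifClass:
    """Classify the principal-site tripeptide.

    Exactly two tripeptides are valid: QPD (GAL class) and EPN (MAN class).
    Anything else — including any middle residue other than proline — is
    INVALID.
    """
    if len(tripeptide) != 3:
        raise ValueError(f"tripeptide must have exactly 3 residues, got {tripeptide!r}")
    tri = tripeptide.upper()
    if tri == "QPD":
        return MotifClass.GAL
    if tri == "EPN":
        return MotifClass.MAN
    return MotifClass.INVALID


def check_cysteines(crd_seq: str, expected: int = 4) -> tuple:
    """Count cysteines and check against the expected conserved number."""
    seq = getattr(crd_seq, "residues", crd_seq)
    if not seq:
        raise ValueError("CRD sequence must be non-empty")
    if expected < 0:
        raise ValueError("expected cysteine count must be >= 0")
    count = seq.count("C")
    return count, count >= expected


def heptad_score(neck_seq: str) -> float:
    """Best-register heptad score of a coiled-coil neck.

    For each of the 7 possible register phases, the fraction of a- and
    d-position residues that are hydrophobic ({L,I,V,M,F,A}) is computed; the
    maximum over phases is returned.
    """
    seq = getattr(neck_seq, "residues", neck_seq)
    if len(seq) < 14:
        raise ValueError(f"neck sequence must have length >= 14, got {len(seq)}")
    best = 0.0
    for phase in range(7):
        positions = [i for i in range(len(seq)) if (i - phase) % 7 in (0, 3)]
        if not positions:
            continue
        frac = sum(1 for i in positions if seq[i] in HYDROPHOBIC) / len(positions)
        best = max(best, frac)
    return best


def call_functional_status(
    acceptor_calls,
    donor_calls,
    motif: MotifClass | None,
    cys_ok: bool | None,
) -> FunctionalStatus:
    """Combine splice-site, binding-motif and fold evidence into one status.

    Defects are counted as: each supplied splice call that is non-canonical
    (and not merely ambiguous from an N in the assembly), plus an INVALID
    binding motif, plus a failed cysteine check. Two or more independent
    defects give PSEUDO_MULTIPLE; a lone splice or binding defect gives
    PSEUDO_SPLICE or PSEUDO_BINDING_SITE. A FUNCTIONAL call requires complete,
    unambiguous evidence: at least one splice call, all canonical, a valid
    motif and an intact cysteine set. Anything less, with no positive defect,
    is INDETERMINATE — missing evidence never upgrades to functional, and a
    positive defect is sufficient even when other evidence is missing.
    """
    acceptor_calls = list(acceptor_calls or [])
    donor_calls = list(donor_calls or [])
    calls = acceptor_calls + donor_calls
    for c in calls:
        if c.kind not in ("donor", "acceptor"):
            raise ValueError(f"unexpected splice-call kind {c.kind!r}")
    if motif is not None and not isinstance(motif, MotifClass):
        raise ValueError(f"motif must be a MotifClass or None, got {motif!r}")

    splice_defects = sum(1 for c in calls if not c.canonical and not c.ambiguous)
    binding_defects = (1 if motif is MotifClass.INVALID else 0) + (
        1 if cys_ok is False else 0
    )
    n_defects = splice_defects + binding_defects

    if n_defects >= 2:
        return FunctionalStatus.PSEUDO_MULTIPLE
    if splice_defects == 1:
        return FunctionalStatus.PSEUDO_SPLICE
    if binding_defects == 1:
        return FunctionalStatus.PSEUDO_BINDING_SITE

    complete = (
        bool(calls)
        and all(c.canonical for c in calls)
        and motif in (MotifClass.GAL, MotifClass.MAN)
        and cys_ok is True
    )
    if not complete:
        return FunctionalStatus.INDETERMINATE
    return (
        FunctionalStatus.FUNCTIONAL_GAL
        if motif is MotifClass.GAL
        else FunctionalStatus.FUNCTIONAL_MAN
    )


def build_crd_report(
    crd_seq,
    motif_offset: int,
    acceptor_calls,
    donor_calls,
    expected_cys: int = 4,
    neck_seq=None,
) -> CRDReport:
    """Convenience wrapper: extract the tripeptide at ``motif_offset`` from the
    CRD sequence, run all checks and combine them into a CRDReport."""
    seq = getattr(crd_seq, "residues", crd_seq)
    tri = seq[motif_offset : motif_offset + 3]
    if len(tri) != 3:
        raise ValueError(
            f"motif offset {motif_offset} leaves fewer than 3 residues in CRD"
        )
    motif = classify_binding_motif(tri)
    count, ok = check_cysteines(seq, expected_cys)
    status = call_functional_status(acceptor_calls, donor_calls, motif, ok)
    heptad = heptad_score(neck_seq) if neck_seq is not None else None
    return CRDReport(
        motif=motif,
        tripeptide=tri,
        cys_count=count,
        cys_ok=ok,
        status=status,
        heptad=heptad,
    )
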