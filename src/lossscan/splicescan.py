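"""Splice-site validation and terminal-exon rescue.

Automated gene annotation can miscall the last exon of a gene when a
fortuitous in-frame acceptor lies between the penultimate exon and the true
terminal exon. The rescue scan enumerates every AG acceptor downstream of the
penultimate exon's donor and scores each by (i) the pyrimidine content of the
tract immediately 5' of the AG, (ii) how well the translation from the
acceptor matches a consensus profile of the expected C-terminal protein
features, and (iii) whether the reading frame stays open. The true terminal
exon of an intact gene outranks decoys on all three.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .genemodels import NucSequence, translate

logger = logging.getLogger(__name__)

PYRIMIDINES = frozenset("CT")


@dataclass(frozen=True)
class SpliceSiteCall:
    """Verdict on one splice site.

    ``canonical`` is True only for GT donors / AG acceptors; a dinucleotide
    containing N is never canonical and carries ``ambiguous=True`` so that
    incomplete genome assemblies are not mistaken for mutations.
    ``ppt_score`` (acceptors only) is the pyrimidine fraction of the window
    immediately 5' of the AG.
    """

    kind: str  # "donor" | "acceptor"
    dinucleotide: str
    canonical: bool
    ambiguous: bool
    ppt_score: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("donor", "acceptor"):
            raise ValueError(f"kind must be 'donor' or 'acceptor', got {self.kind!r}")
        if self.kind == "donor" and self.ppt_score is not None:
            raise ValueError("ppt_score applies to acceptors only")


@dataclass(frozen=True)
class AcceptorCandidate:
    """A putative terminal-exon acceptor found by the rescue scan."""

    acceptor_pos: int
    ppt_score: float
    frame_ok: bool
    orf_len: int
    profile_matches: int
    total_score: float


@dataclass(frozen=True)
class CrdCterminalProfile:
    """Expected features of the translated terminal exon.

    ``features`` is an ordered tuple of (offset, allowed-residues) pairs with
    strictly increasing non-negative offsets into the translation of the
    candidate exon. For a galactose-type CRD this includes the QPD tripeptide
    slot and the conserved cysteines.
    """

    features: tuple

    def __post_init__(self) -> None:
        feats = []
        last = -1
        for off, residues in self.features:
            if off < 0:
                raise ValueError(f"feature offset {off} is negative")
            if off <= last:
                raise ValueError("feature offsets must be strictly increasing")
            last = off
            feats.append((off, frozenset(residues)))
        object.__setattr__(self, "features", tuple(feats))

    def __len__(self) -> int:
        return len(self.features)

    def count_matches(self, protein: str) -> int:
        n = 0
        for off, residues in self.features:
            if off < len(protein) and protein[off] in residues:
                n += 1
        return n


@dataclass(frozen=True)
class RescueParams:
    """Tunable weights and limits for the rescue scan."""

    ppt_window: int = 20
    span: int = 10_000
    min_codons: int = 30
    w_ppt: float = 1.0
    w_profile: float = 1.0
    w_frame: float = 0.5


def call_donor(locus: NucSequence, intron_start_pos: int) -> SpliceSiteCall:
    """Call the donor site whose intron begins at ``intron_start_pos``."""
    if intron_start_pos < 0 or intron_start_pos + 2 > len(locus):
        raise IndexError(
            f"donor dinucleotide [{intron_start_pos},{intron_start_pos + 2}) "
            f"outside locus of length {len(locus)}"
        )
    dinuc = locus.residues[intron_start_pos : intron_start_pos + 2]
    ambiguous = "N" in dinuc
    return SpliceSiteCall(
        kind="donor",
        dinucleotide=dinuc,
        canonical=(dinuc == "GT"),
        ambiguous=ambiguous,
    )


def call_acceptor(
    locus: NucSequence, acceptor_pos: int, ppt_window: int = 20
) -> SpliceSiteCall:
    """Call the acceptor preceding the exon that starts at ``acceptor_pos``.

    ``ppt_score`` is the C+T fraction over the ``ppt_window`` bases immediately
    5' of the AG dinucleotide.
    """
    if ppt_window < 1:
        raise ValueError("ppt_window must be >= 1")
    if acceptor_pos - 2 - ppt_window < 0 or acceptor_pos > len(locus):
        raise IndexError(
            f"acceptor at {acceptor_pos} leaves no room for dinucleotide plus "
            f"{ppt_window}-base tract"
        )
    dinuc = locus.residues[acceptor_pos - 2 : acceptor_pos]
    window = locus.residues[acceptor_pos - 2 - ppt_window : acceptor_pos - 2]
    ppt = sum(1 for b in window if b in PYRIMIDINES) / ppt_window
    ambiguous = "N" in dinuc
    return SpliceSiteCall(
        kind="acceptor",
        dinucleotide=dinuc,
        canonical=(dinuc == "AG"),
        ambiguous=ambiguous,
        ppt_score=ppt,
    )


def rescue_terminal_exon(
    locus: NucSequence,
    search_start: int,
    frame: int,
    profile: CrdCterminalProfile,
    params: RescueParams = RescueParams(),
) -> list:
    """Scan downstream of ``search_start`` for plausible terminal-exon acceptors.

    Every position preceded by an AG within the search span yields a candidate.
    ``frame`` is the number of bases to skip after the acceptor to reach the
    first complete codon (the GFF-style phase fixed by the upstream coding
    sequence, shared by all candidates since they share the donor).

    Candidates are scored
    ``w_ppt * ppt_score + w_profile * (matches/|profile|) + w_frame * frame_ok``
    and returned sorted by score descending, ties broken by smaller position.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    if search_start < 0 or search_start > len(locus):
        raise IndexError(f"search_start {search_start} outside locus")
    span_end = search_start + params.span
    if span_end > len(locus):
        logger.warning(
            "search span [%d, %d) exceeds locus length %d; truncated",
            search_start,
            span_end,
            len(locus),
        )
        span_end = len(locus)

    seq = locus.residues
    candidates = []
    for pos in range(search_start + 2, span_end + 1):
        if seq[pos - 2 : pos] != "AG":
            continue
        if pos - 2 - params.ppt_window < 0:
            continue
        call = call_acceptor(locus, pos, params.ppt_window)
        tail = seq[pos + frame :]
        protein = translate(tail)
        stop = protein.find("*")
        orf_len = len(protein) if stop == -1 else stop
        frame_ok = orf_len >= params.min_codons
        coding = protein if stop == -1 else protein[:stop]
        matches = profile.count_matches(coding)
        total = (
            params.w_ppt * call.ppt_score
            + params.w_profile * (matches / len(profile) if len(profile) else 0.0)
            + params.w_frame * (1.0 if frame_ok else 0.0)
        )
        candidates.append(
            AcceptorCandidate(
                acceptor_pos=pos,
                ppt_score=call.ppt_score,
                frame_ok=frame_ok,
                orf_len=orf_len,
                profile_matches=matches,
                total_score=total,
            )
        )
    candidates.sort(key=lambda c: (-c.total_score, c.acceptor_pos))
    return candidates
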