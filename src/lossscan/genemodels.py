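"""Sequence and gene-model primitives plus FASTA/GFF3 I/O.

Coordinates are 0-based half-open internally; GFF3 reading/writing converts
to and from the standard's 1-based inclusive columns at the boundary.
Gene models are single-transcript: alternative isoforms are separate models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NUC_ALPHABET = frozenset("ACGTN")
PROT_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FastaParseError(ValueError):
    """Raised when a FASTA file is syntactically malformed."""


class SequenceAlphabetError(ValueError):
    """Raised when a residue outside the declared alphabet is encountered."""


class GeneModelError(ValueError):
    """Raised when exon coordinates violate gene-model invariants."""


def _validate_residues(record_id: str, residues: str, alphabet: frozenset) -> None:
    for i, ch in enumerate(residues):
        if ch not in alphabet:
            raise SequenceAlphabetError(
                f"record {record_id!r}: illegal residue {ch!r} at position {i + 1}"
            )


@dataclass(frozen=True)
class NucSequence:
    """A named nucleotide sequence over {A,C,G,T,N}."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        if not self.residues:
            raise SequenceAlphabetError(f"record {self.id!r}: empty sequence")
        _validate_residues(self.id, self.residues, NUC_ALPHABET)

    def __len__(self) -> int:
        return len(self.residues)

    def slice(self, start: int, end: int) -> str:
        if start < 0 or end > len(self.residues):
            raise IndexError(
                f"[{start}, {end}) outside locus {self.id!r} of length {len(self)}"
            )
        return self.residues[start:end]

    def reverse_complement(self) -> "NucSequence":
        return NucSequence(self.id, self.residues.translate(_COMPLEMENT)[::-1])


@dataclass(frozen=True)
class ProtSequence:
    """A named amino-acid sequence over the 20 standard residues plus X."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        if not self.residues:
            raise SequenceAlphabetError(f"record {self.id!r}: empty sequence")
        _validate_residues(self.id, self.residues, PROT_ALPHABET)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Exon:
    """One exon: [start, end) on the locus, ordinal index in transcription order,
    and the GFF-style phase (bases to skip to reach the first complete codon)."""

    start: int
    end: int
    index: int
    phase: int = 0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise GeneModelError(f"exon {self.index}: start {self.start} >= end {self.end}")
        if self.phase not in (0, 1, 2):
            raise GeneModelError(f"exon {self.index}: phase {self.phase} not in {{0,1,2}}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """A single-transcript gene model on one locus.

    Exons are stored sorted ascending by coordinate and must not overlap;
    ``index`` runs 1..n in transcription order (so on the minus strand the
    5'-most exon is the one with the largest coordinates).
    """

    locus_id: str
    strand: str
    exons: tuple

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise GeneModelError(f"strand must be '+' or '-', got {self.strand!r}")
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        object.__setattr__(self, "exons", exons)
        if not exons:
            raise GeneModelError("gene model must contain at least one exon")
        for a, b in zip(exons, exons[1:]):
            if a.end > b.start:
                raise GeneModelError(
                    f"exons overlap: [{a.start},{a.end}) and [{b.start},{b.end})"
                )
        indices = [e.index for e in self.transcription_order()]
        if indices != list(range(1, len(exons) + 1)):
            raise GeneModelError(
                f"exon indices must be consecutive 1..n in transcription order, got {indices}"
            )

    def transcription_order(self) -> tuple:
        """Exons ordered 5' to 3' along the transcript."""
        return self.exons if self.strand == "+" else tuple(reversed(self.exons))

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exon(self, index: int) -> Exon:
        for e in self.exons:
            if e.index == index:
                return e
        raise KeyError(f"no exon with index {index}")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path, kind: str = "nucleotide"):
    """Read a FASTA file into NucSequence or ProtSequence records.

    ``kind`` declares the expected alphabet: "nucleotide" or "protein".
    Residues are upper-cased; an illegal residue raises SequenceAlphabetError
    naming the record and 1-based position.
    """
    path = Path(path)
    text = path.read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip():
            if not line.startswith(">"):
                raise FastaParseError(f"{path}: line {lineno}: expected '>' header")
            break
    cls = {"nucleotide": NucSequence, "protein": ProtSequence}.get(kind)
    if cls is None:
        raise ValueError(f"kind must be 'nucleotide' or 'protein', got {kind!r}")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(cls(rec.id, str(rec.seq)))
    return records


def write_fasta(path, sequences: Iterable) -> None:
    """Write sequences as FASTA; round-trips exactly through read_fasta."""
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in sequences]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3

_GFF3_COLUMNS = 9


def _parse_attributes(col: str) -> dict:
    attrs = {}
    for part in col.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            k, v = part.split("=", 1)
            attrs[k.strip()] = v.strip()
    return attrs


def read_gff3(path, locus: NucSequence | None = None):
    """Read exon features from a GFF3 file into GeneModel objects.

    Exons are grouped into one model per ``Parent`` attribute (falling back to
    ``ID``, then to the seqid). GFF3 1-based inclusive coordinates are converted
    to internal 0-based half-open ones. If ``locus`` is given, exons must lie
    within its bounds and match its id.
    """
    path = Path(path)
    groups: dict = {}
    strands: dict = {}
    seqids: dict = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != _GFF3_COLUMNS:
            raise GeneModelError(f"{path}: line {lineno}: expected 9 tab-separated columns")
        seqid, _source, ftype, start, end, _score, strand, phase, attr_col = cols
        if ftype != "exon":
            continue
        attrs = _parse_attributes(attr_col)
        key = attrs.get("Parent") or attrs.get("ID") or seqid
        start0 = int(start) - 1
        end0 = int(end)
        if locus is not None:
            if seqid != locus.id:
                raise GeneModelError(
                    f"{path}: line {lineno}: seqid {seqid!r} does not match locus {locus.id!r}"
                )
            if start0 < 0 or end0 > len(locus):
                raise GeneModelError(
                    f"{path}: line {lineno}: exon [{start0},{end0}) outside locus bounds"
                )
        ph = 0 if phase in (".", "") else int(phase)
        groups.setdefault(key, []).append((start0, end0, ph))
        strands.setdefault(key, strand)
        seqids.setdefault(key, seqid)

    models = []
    for key, exon_coords in groups.items():
        strand = strands[key]
        exon_coords.sort()
        # index in transcription order
        ordered = exon_coords if strand == "+" else list(reversed(exon_coords))
        exons = []
        for idx, (s, e, ph) in enumerate(ordered, start=1):
            exons.append(Exon(start=s, end=e, index=idx, phase=ph))
        models.append(GeneModel(locus_id=seqids[key], strand=strand, exons=tuple(exons)))
    return models


def write_gff3(path, models: Sequence[GeneModel], source: str = "lossscan") -> None:
    """Write gene models as GFF3 exon features (round-trips through read_gff3)."""
    lines = ["##gff-version 3"]
    for m, model in enumerate(models, start=1):
        parent = f"model{m}"
        for e in model.exons:
            attrs = f"ID={parent}.exon{e.index};Parent={parent}"
            lines.append(
                "\t".join(
                    [
                        model.locus_id,
                        source,
                        "exon",
                        str(e.start + 1),
                        str(e.end),
                        ".",
                        model.strand,
                        str(e.phase),
                        attrs,
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------


def splice_transcript(locus: NucSequence, model: GeneModel) -> NucSequence:
    """Concatenate exon sequences in transcription order.

    Minus-strand models yield the reverse complement of the concatenated
    plus-strand exon sequence, i.e. the mRNA-sense sequence.
    """
    for e in model.exons:
        if e.start < 0 or e.end > len(locus):
            raise GeneModelError(
                f"exon [{e.start},{e.end}) outside locus {locus.id!r} of length {len(locus)}"
            )
    joined = "".join(locus.residues[e.start:e.end] for e in model.exons)
    if model.strand == "-":
        joined = joined.translate(_COMPLEMENT)[::-1]
    return NucSequence(f"{locus.id}|transcript", joined)


def translate(nuc: str) -> str:
    """Translate a nucleotide string, trimming any incomplete final codon.

    Stops are rendered as '*'; codons containing N translate to X.
    """
    usable = len(nuc) - (len(nuc) % 3)
    if usable == 0:
        return ""
    return str(Seq(nuc[:usable]).translate())
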