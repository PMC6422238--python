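"""Seeded generators for loci, junction tables, glycan arrays and expression
tables with recorded ground truth.

The locus generator emulates a seven-exon type-II receptor gene: exons 1-4
encode cytoplasmic tail, transmembrane anchor, spacer and neck, exons 5-7 the
~130-residue CRD, with canonical GT-AG introns, a pyrimidine-rich tract ahead
of each acceptor, and (optionally) a decoy in-frame acceptor in the final
intron that mimics the spurious "exon X" picked up by automated annotation.
Inactivating mutations can be implanted: the final acceptor AG->GG, the
final donor GT->AT, binding-motif codon substitutions, or wholesale removal
of the terminal exon. All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .crdclass import FunctionalStatus, MotifClass, classify_binding_motif
from .genemodels import Exon, GeneModel, NucSequence, ProtSequence, translate
from .glycanarray import ArraySpot, EpitopeClass, classify_epitope, parse_iupac, summarize_spot
from .junctions import UNSPLICED, JunctionRecord
from .splicescan import CrdCterminalProfile

# one representative codon per amino acid, for deterministic implants
CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCA", "Q": "CAA", "R": "CGT",
    "S": "AGC", "T": "ACA", "V": "GTG", "W": "TGG", "Y": "TAT",
}

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
SENSE_CODONS = tuple(
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
)

ACCEPTOR_GG = "ACCEPTOR_GG"
DONOR_AT = "DONOR_AT"
DELETE_EXON7 = "DELETE_EXON7"
DELETED_EXON = "DELETED_EXON"

PPT_LEN = 20
# offsets (codons) into the translated terminal exon of the consensus features
MOTIF_EXON_OFFSET = 3
CYS_EXON_OFFSETS = (10, 25)
# extra conserved cysteines implanted in the CRD upstream of the final exon,
# as codon offsets from the CRD start
CYS_CRD_OFFSETS = (9, 59)

BACKGROUND_TPM = 1.0
DEFAULT_TISSUES = ("liver", "spleen", "lung", "kidney", "heart", "brain", "lymph_node")


@dataclass(frozen=True)
class LocusSpec:
    """Blueprint for one synthetic locus. Same spec + seed => identical locus."""

    n_exons: int = 7
    exon_lengths: tuple = (120, 81, 72, 150, 141, 131, 121)
    intron_lengths: tuple = (400, 350, 300, 320, 280, 300)
    motif: str = "QPD"
    mutations: tuple = ()
    decoy_exon_x: bool = True
    utr5: int = 30
    utr3: int = 90
    seed: int = 0


@dataclass(frozen=True)
class TruthLabel:
    """Recorded ground truth for a generated locus."""

    expected_status: FunctionalStatus
    expected_chosen: str  # "exon7" or UNSPLICED
    acceptor_offset: int | None  # locus offset of the terminal exon's first base
    decoy_acceptor_pos: int | None
    donor_pos: int | None  # locus offset of the final intron's first base
    frame: int  # bases to skip after the acceptor to reach a complete codon
    motif_offset: int  # codon offset of the tripeptide within the CRD protein
    tripeptide: str
    crd_protein: ProtSequence
    annotation: str | None = None


def consensus_profile(spec: LocusSpec = LocusSpec()) -> CrdCterminalProfile:
    """Expected features of the translated terminal exon: the (unmutated)
    binding-motif tripeptide and the implanted conserved cysteines."""
    q, p, d = spec.motif.upper()
    features = [
        (MOTIF_EXON_OFFSET, q),
        (MOTIF_EXON_OFFSET + 1, p),
        (MOTIF_EXON_OFFSET + 2, d),
    ]
    for off in CYS_EXON_OFFSETS:
        features.append((off, "C"))
    return CrdCterminalProfile(features=tuple(sorted(features)))


def _random_bases(rng, n: int) -> str:
    return "".join(rng.choice(list(_BASES), size=n)) if n > 0 else ""


def _random_codons(rng, n: int) -> list:
    idx = rng.integers(0, len(SENSE_CODONS), size=n)
    return [SENSE_CODONS[i] for i in idx]


def _ppt(rng) -> str:
    # all-pyrimidine tract: saturates the acceptor consensus and guarantees
    # the implanted acceptor outranks any fortuitous AG
    return "".join(rng.choice(["C", "T"], size=PPT_LEN, p=[0.4, 0.6]))


def _purine_window(rng, n: int = PPT_LEN) -> str:
    return "".join(rng.choice(list(_BASES), size=n, p=[0.4, 0.1, 0.35, 0.15]))


def _parse_mutations(mutations) -> tuple:
    splice, motif_swap, delete = [], None, False
    for m in mutations:
        if m in (ACCEPTOR_GG, DONOR_AT):
            splice.append(m)
        elif m == DELETE_EXON7:
            delete = True
        elif isinstance(m, str) and m.startswith("MOTIF:"):
            motif_swap = m.split(":", 1)[1].upper()
            if len(motif_swap) != 3 or any(ch not in CODON for ch in motif_swap):
                raise ValueError(f"bad motif mutation {m!r}")
        else:
            raise ValueError(f"unknown mutation {m!r}")
    return tuple(splice), motif_swap, delete


def make_locus(spec: LocusSpec):
    """Generate (locus, model, truth) for the given spec.

    The coding sequence is random sense codons with the binding motif and
    conserved cysteines implanted at fixed offsets; introns are canonical
    GT..AG with an all-pyrimidine tract before each acceptor, except where a
    splice mutation is requested.
    """
    if len(spec.exon_lengths) != spec.n_exons:
        raise ValueError("exon_lengths must have n_exons entries")
    if len(spec.intron_lengths) != spec.n_exons - 1:
        raise ValueError("intron_lengths must have n_exons - 1 entries")
    total = sum(spec.exon_lengths)
    if total % 3 != 0:
        raise ValueError("total coding length must be a multiple of 3")
    if any(il < PPT_LEN + 30 for il in spec.intron_lengths):
        raise ValueError(f"introns must be at least {PPT_LEN + 30} nt")
    n_codons = total // 3
    final_len = spec.exon_lengths[-1]
    cum_before = total - final_len
    frame = (3 - cum_before % 3) % 3
    exon7_c0 = (cum_before + frame) // 3  # first complete codon of final exon
    if exon7_c0 + max(CYS_EXON_OFFSETS) + 1 >= n_codons:
        raise ValueError("final exon too short for the planned motif and cysteines")

    splice_muts, motif_swap, delete = _parse_mutations(spec.mutations)
    tripeptide = motif_swap if motif_swap else spec.motif.upper()
    if len(tripeptide) != 3:
        raise ValueError("motif must be a tripeptide")

    rng = np.random.default_rng(spec.seed)
    codons = _random_codons(rng, n_codons)
    codons[-1] = "TAA"
    # CRD = exons 5..7 in the default architecture; fall back to the final
    # three exons for custom architectures
    crd_first_exon = max(0, spec.n_exons - 3)
    crd_start_nt = sum(spec.exon_lengths[:crd_first_exon])
    crd_c0 = (crd_start_nt + 2) // 3
    for off in CYS_CRD_OFFSETS:
        c = crd_c0 + off
        if c < exon7_c0:
            codons[c] = CODON["C"]
    for k, aa in enumerate(tripeptide):
        codons[exon7_c0 + MOTIF_EXON_OFFSET + k] = CODON[aa]
    for off in CYS_EXON_OFFSETS:
        codons[exon7_c0 + off] = CODON["C"]
    cds = "".join(codons)

    # assemble the locus
    parts = [_random_bases(rng, spec.utr5)]
    pos = spec.utr5
    exons = []
    cds_cursor = 0
    coding_before = 0
    donor_pos = None
    acceptor_pos = None
    for i in range(spec.n_exons):
        length = spec.exon_lengths[i]
        phase = (3 - coding_before % 3) % 3
        exons.append(Exon(start=pos, end=pos + length, index=i + 1, phase=phase))
        parts.append(cds[cds_cursor : cds_cursor + length])
        cds_cursor += length
        coding_before += length
        pos += length
        if i < spec.n_exons - 1:
            final_intron = i == spec.n_exons - 2
            il = spec.intron_lengths[i]
            donor = "AT" if (final_intron and DONOR_AT in splice_muts) else "GT"
            acceptor = "GG" if (final_intron and ACCEPTOR_GG in splice_muts) else "AG"
            if final_intron:
                donor_pos = pos
            body_len = il - 2 - PPT_LEN - 2
            if final_intron and spec.decoy_exon_x:
                decoy_orf = "".join(_random_codons(rng, 32))
                decoy_block = _purine_window(rng) + "AG" + _random_bases(rng, frame) + decoy_orf
                if body_len < len(decoy_block) + 20:
                    raise ValueError("final intron too short for the decoy exon")
                lead = _random_bases(rng, 10)
                tail_len = body_len - len(decoy_block) - 10
                body = lead + decoy_block + _random_bases(rng, tail_len)
                decoy_acceptor_pos = pos + 2 + 10 + PPT_LEN + 2
            else:
                body = _random_bases(rng, body_len)
            parts.append(donor + body + _ppt(rng) + acceptor)
            if final_intron:
                acceptor_pos = pos + il
            pos += il
    parts.append(_random_bases(rng, spec.utr3))
    residues = "".join(parts)
    if not spec.decoy_exon_x:
        decoy_acceptor_pos = None

    annotation = None
    if delete:
        # erase the terminal exon and its acceptor; the gene model keeps only
        # the upstream exons, mimicking genomes where no final exon is found
        chars = list(residues)
        wipe_from = acceptor_pos - 2 - PPT_LEN
        wipe_to = exons[-1].end
        chars[wipe_from:wipe_to] = _random_bases(rng, wipe_to - wipe_from)
        residues = "".join(chars)
        exons = exons[:-1]
        acceptor_pos = None
        annotation = DELETED_EXON

    locus = NucSequence(f"synthetic_locus_seed{spec.seed}", residues)
    model = GeneModel(locus_id=locus.id, strand="+", exons=tuple(exons))

    crd_protein = ProtSequence(
        f"{locus.id}|crd", translate(cds[crd_c0 * 3 : (n_codons - 1) * 3])
    )
    motif_offset = exon7_c0 + MOTIF_EXON_OFFSET - crd_c0

    motif_class = classify_binding_motif(tripeptide)
    n_splice = len(set(splice_muts))
    binding_defect = motif_class is MotifClass.INVALID
    if delete:
        status = FunctionalStatus.INDETERMINATE
    elif n_splice + int(binding_defect) >= 2:
        status = FunctionalStatus.PSEUDO_MULTIPLE
    elif n_splice == 1:
        status = FunctionalStatus.PSEUDO_SPLICE
    elif binding_defect:
        status = FunctionalStatus.PSEUDO_BINDING_SITE
    else:
        status = (
            FunctionalStatus.FUNCTIONAL_GAL
            if motif_class is MotifClass.GAL
            else FunctionalStatus.FUNCTIONAL_MAN
        )
    chosen = "exon7" if (n_splice == 0 and not delete) else UNSPLICED

    truth = TruthLabel(
        expected_status=status,
        expected_chosen=chosen,
        acceptor_offset=acceptor_pos,
        decoy_acceptor_pos=decoy_acceptor_pos,
        donor_pos=donor_pos,
        frame=frame,
        motif_offset=motif_offset,
        tripeptide=tripeptide,
        crd_protein=crd_protein,
        annotation=annotation,
    )
    return locus, model, truth


def simulate_junctions(model: GeneModel, truth: TruthLabel, depth: float, seed: int):
    """Junction tables consistent with a locus's splicing status.

    Spliced junctions of a functional locus carry zero-truncated Poisson(depth)
    spanning reads (a junction present in the transcript is seen at least
    once); an UNSPLICED truth emits no reads at the final junction and at most
    one background read elsewhere. depth == 0 yields an empty table.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if depth == 0:
        return []
    rng = np.random.default_rng(seed)
    exon_pairs = list(zip(model.transcription_order(), model.transcription_order()[1:]))
    records = []
    spliced = truth.expected_chosen == "exon7"
    for k, (a, b) in enumerate(exon_pairs):
        final = k == len(exon_pairs) - 1
        if spliced:
            reads = 0
            while reads == 0:
                reads = int(rng.poisson(depth))
        elif final:
            continue
        else:
            reads = int(rng.integers(0, 2))
        if reads > 0:
            records.append(
                JunctionRecord(donor_pos=a.end, acceptor_pos=b.start, reads=reads)
            )
    return records


# ---------------------------------------------------------------------------
# Glycan arrays


@dataclass(frozen=True)
class ReceptorProfile:
    """Epitope-class signal profile of a receptor on the array.

    Replicate intensities for a glycan of class c are drawn as
    ``background + class_signal[c]`` plus zero-mean Gaussian noise, clipped at
    zero (scanner intensities are non-negative)."""

    class_signal: dict
    noise_sd: float = 500.0
    background: float = 150.0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.class_signal.values()):
            raise ValueError("class signals must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def mean_for(self, epitope: EpitopeClass) -> float:
        return self.background + self.class_signal.get(epitope, 0.0)


def murine_like_profile() -> ReceptorProfile:
    """Broad galactose-type binding: Lewis and GalNAc termini strongest, other
    galactose termini intermediate."""
    return ReceptorProfile(
        class_signal={
            EpitopeClass.LEWIS: 30000.0,
            EpitopeClass.GALNAC: 28000.0,
            EpitopeClass.GAL: 12000.0,
            EpitopeClass.OTHER: 0.0,
        }
    )


def bovine_like_profile() -> ReceptorProfile:
    """Strongly fucose-biased binding: Lewis termini dominate everything else."""
    return ReceptorProfile(
        class_signal={
            EpitopeClass.LEWIS: 40000.0,
            EpitopeClass.GALNAC: 6000.0,
            EpitopeClass.GAL: 5000.0,
            EpitopeClass.OTHER: 0.0,
        }
    )


# A small CFG-style panel spanning the four epitope classes.
DEFAULT_GLYCANS = (
    # terminal Lewis-x / Lewis-a
    "Galb1-4(Fuca1-3)GlcNAcb1-3Galb1-4Glc-Sp0",
    "Galb1-3(Fuca1-4)GlcNAcb1-3Galb1-4Glc-Sp8",
    "Galb1-4(Fuca1-3)GlcNAc-Sp8",
    "Galb1-3(Fuca1-4)GlcNAc-Sp8",
    "Galb1-4(Fuca1-3)GlcNAcb1-3Galb1-4(Fuca1-3)GlcNAcb1-3Galb1-4Glc-Sp0",
    "Galb1-4(Fuca1-3)GlcNAcb1-2Mana1-3(Galb1-4(Fuca1-3)GlcNAcb1-2Mana1-6)Manb1-4GlcNAcb1-4GlcNAc-Sp12",
    "Galb1-3(Fuca1-4)GlcNAcb1-2Mana1-3(Galb1-3(Fuca1-4)GlcNAcb1-2Mana1-6)Manb1-4GlcNAcb1-4GlcNAc-Sp12",
    "Galb1-4(Fuca1-3)GlcNAcb1-6Galb1-4Glc-Sp8",
    "Galb1-3(Fuca1-4)GlcNAcb1-3Galb1-3GlcNAc-Sp0",
    "Galb1-4(Fuca1-3)GlcNAcb1-3Galb1-3GlcNAc-Sp0",
    "Galb1-4(Fuca1-3)GlcNAcb1-4GlcNAc-Sp8",
    "Galb1-3(Fuca1-4)GlcNAcb1-6Galb1-4Glc-Sp8",
    # other terminal galactose with free 3-/4-OH
    "Galb1-4Glc-Sp8",
    "Galb1-4GlcNAc-Sp0",
    "Galb1-3GlcNAcb1-3Galb1-4Glc-Sp8",
    "Galb1-4GlcNAcb1-2Man-Sp0",
    "Gala1-3Galb1-4GlcNAc-Sp8",
    "Galb1-4GlcNAcb1-2Mana1-3(Galb1-4GlcNAcb1-2Mana1-6)Manb1-4GlcNAcb1-4GlcNAc-Sp12",
    "Galb1-3GalNAc-Sp8",
    "Gala1-4Galb1-4Glc-Sp0",
    "Galb1-4GlcNAcb1-3Galb1-4GlcNAc-Sp0",
    "Galb1-4GlcNAcb1-6Galb1-4GlcNAc-Sp0",
    "(6S)Galb1-4GlcNAc-Sp0",
    "Galb1-3GlcNAc-Sp8",
    # terminal GalNAc with free 3-/4-OH
    "GalNAcb1-4GlcNAc-Sp0",
    "GalNAca1-3Galb1-4Glc-Sp8",
    "GalNAcb1-4GlcNAcb1-2Man-Sp8",
    "GalNAcb1-3Gal-Sp8",
    "GalNAca1-3GalNAc-Sp8",
    "GalNAcb1-4GlcNAcb1-2Mana1-3(GalNAcb1-4GlcNAcb1-2Mana1-6)Manb1-4GlcNAcb1-4GlcNAc-Sp12",
    "GalNAca1-3(Fuca1-2)Galb1-4Glc-Sp0",
    "GalNAcb1-3Gala1-4Galb1-4Glc-Sp8",
    "GalNAca1-6Gal-Sp8",
    "GalNAcb1-6GalNAc-Sp8",
    # none of the above
    "Mana1-3(Mana1-6)Manb1-4GlcNAcb1-4GlcNAc-Sp12",
    "Mana1-2Mana1-3Man-Sp8",
    "Mana1-6Manb1-4GlcNAc-Sp0",
    "Neu5Aca2-3Galb1-4GlcNAc-Sp8",
    "Neu5Aca2-6Galb1-4GlcNAcb1-3Galb1-4Glc-Sp0",
    "Neu5Aca2-3Galb1-4(Fuca1-3)GlcNAcb1-3Galb1-4Glc-Sp8",
    "Neu5Gca2-6Galb1-4GlcNAc-Sp8",
    "Glcb1-4Glc-Sp8",
    "GlcNAcb1-4GlcNAcb1-4GlcNAc-Sp8",
    "Fuca1-2Galb1-4Glc-Sp0",
    "(3S)Galb1-4GlcNAc-Sp0",
    "GlcNAcb1-2Mana1-3(GlcNAcb1-2Mana1-6)Manb1-4GlcNAcb1-4GlcNAc-Sp12",
    "Xylb1-4Xylb1-4Xyl-Sp8",
    "Neu5Aca2-3Galb1-3GlcNAc-Sp8",
)


def simulate_array(profile: ReceptorProfile, glycans=DEFAULT_GLYCANS, seed: int = 0):
    """Simulate one array screen: six replicates per glycan, class-dependent
    signal plus truncated Gaussian noise. Returns summarized, classified spots."""
    rng = np.random.default_rng(seed)
    spots = []
    for gid, structure in enumerate(glycans, start=1):
        epitope = classify_epitope(parse_iupac(structure))
        reps = rng.normal(profile.mean_for(epitope), profile.noise_sd, size=6)
        reps = np.clip(reps, 0.0, None)
        mean, sd = summarize_spot(reps)
        spots.append(
            ArraySpot(
                glycan_id=gid,
                structure=structure,
                replicates=tuple(float(v) for v in reps),
                mean=mean,
                sd=sd,
                epitope=epitope,
            )
        )
    return spots


def write_array_table(path, spots) -> None:
    df = pd.DataFrame(
        {
            "glycan_id": [s.glycan_id for s in spots],
            "structure": [s.structure for s in spots],
            **{
                f"rfu_{i + 1}": [s.replicates[i] for s in spots]
                for i in range(len(spots[0].replicates))
            },
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Expression

LIVER_RESTRICTED = "LIVER_RESTRICTED"
SPLEEN_DOMINANT = "SPLEEN_DOMINANT"
ABSENT = "ABSENT"


def simulate_expression(pattern: str, tissues=DEFAULT_TISSUES, seed: int = 0) -> pd.DataFrame:
    """Tissue abundance tables for three archetypes: Kupffer-cell-restricted
    (liver >= 1000x any other tissue), spleen-dominant, or background-only."""
    tissues = list(tissues)
    if "liver" not in tissues or "spleen" not in tissues:
        raise ValueError("tissue panel must include liver and spleen")
    rng = np.random.default_rng(seed)
    values = {}
    if pattern == LIVER_RESTRICTED:
        for t in tissues:
            values[t] = float(rng.uniform(0.5, 2.0))
        values["liver"] = float(rng.uniform(2500.0, 3500.0))
    elif pattern == SPLEEN_DOMINANT:
        for t in tissues:
            values[t] = float(rng.uniform(0.5, 8.0))
        values["spleen"] = float(rng.uniform(40.0, 60.0))
        values["liver"] = float(rng.uniform(10.0, 25.0))
    elif pattern == ABSENT:
        for t in tissues:
            values[t] = float(rng.uniform(0.0, 0.5 * BACKGROUND_TPM))
    else:
        raise ValueError(f"unknown expression pattern {pattern!r}")
    return pd.DataFrame({"tissue": tissues, "abundance": [values[t] for t in tissues]})
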