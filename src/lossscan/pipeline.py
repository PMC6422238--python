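"""Per-species evidence accumulation and the species-panel summary.

Each species run walks the same evidentiary chain: validate the splice sites
flanking the terminal exon, rescue-scan for the true terminal exon, tally
junction-read support for competing terminal exons, classify the CRD, and
combine everything into a functional / pseudogene / indeterminate verdict.
Absent inputs degrade the verdict toward INDETERMINATE; they are never
guessed. A positive inactivating defect, however, is sufficient for a
pseudogene call even when other evidence is missing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from .crdclass import (
    CRDReport,
    FunctionalStatus,
    build_crd_report,
    call_functional_status,
)
from .genemodels import GeneModel, NucSequence
from .junctions import AMBIGUOUS, UNSPLICED, SplicingCall, select_terminal_exon
from .splicescan import (
    CrdCterminalProfile,
    RescueParams,
    call_acceptor,
    call_donor,
    rescue_terminal_exon,
)

logger = logging.getLogger(__name__)

FUNCTIONAL = "FUNCTIONAL"
PSEUDOGENE = "PSEUDOGENE"
INDETERMINATE = "INDETERMINATE"

RESTRICTED = "RESTRICTED"
NOT_RESTRICTED = "NOT_RESTRICTED"

DELETED_EXON = "DELETED_EXON"


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and optional knowledge shared across species runs."""

    ppt_window: int = 20
    min_reads: int = 2
    expected_cys: int = 4
    expected_n_exons: int = 7
    motif_offset: int | None = None  # tripeptide offset within the CRD protein
    profile: CrdCterminalProfile | None = None
    rescue: RescueParams = field(default_factory=RescueParams)
    extra_candidates: dict = field(default_factory=dict)  # e.g. {"exonX": pos}
    specificity_threshold: float = 100.0


@dataclass
class SpeciesReport:
    species: str
    splice_calls: list
    rescue: list | None
    rescue_credible: bool | None
    splicing: SplicingCall | None
    crd: CRDReport | None
    status: FunctionalStatus
    verdict: str
    annotation: str | None = None


@dataclass(frozen=True)
class SpecificityResult:
    focal: str
    ratio: float
    infinite: bool
    pattern: str
    threshold: float


def _to_plus_strand(locus: NucSequence, model: GeneModel):
    """Mirror a minus-strand model onto the reverse complement so that all
    downstream splice-site arithmetic runs on the transcribed strand."""
    if model.strand == "+":
        return locus, model
    n = len(locus)
    flipped = locus.reverse_complement()
    from .genemodels import Exon

    exons = []
    for e in model.exons:
        exons.append(Exon(start=n - e.end, end=n - e.start, index=e.index, phase=e.phase))
    return flipped, GeneModel(locus_id=model.locus_id, strand="+", exons=tuple(exons))


def _verdict_for(status: FunctionalStatus, splicing: SplicingCall | None) -> str:
    if status.value.startswith("PSEUDO"):
        return PSEUDOGENE
    if status.value.startswith("FUNCTIONAL"):
        # transcript evidence, when present, must corroborate a functional call
        if splicing is not None and splicing.chosen in (UNSPLICED, AMBIGUOUS):
            return INDETERMINATE
        return FUNCTIONAL
    return INDETERMINATE


def run_species(
    species: str,
    locus: NucSequence,
    model: GeneModel,
    junctions=None,
    protein=None,
    config: PipelineConfig = PipelineConfig(),
) -> SpeciesReport:
    """Run the full evidentiary chain for one species locus."""
    if model.locus_id != locus.id:
        raise ValueError(
            f"model locus_id {model.locus_id!r} does not match locus {locus.id!r}"
        )
    locus, model = _to_plus_strand(locus, model)
    trans = model.transcription_order()
    has_final = model.n_exons >= config.expected_n_exons

    # splice calls for every intron; the final intron's calls feed the status
    splice_calls = []
    final_donor_call = None
    final_acceptor_call = None
    for k, (a, b) in enumerate(zip(trans, trans[1:])):
        donor = call_donor(locus, a.end)
        acceptor = call_acceptor(locus, b.start, config.ppt_window)
        splice_calls.extend([donor, acceptor])
        if k == len(trans) - 2:
            final_donor_call, final_acceptor_call = donor, acceptor
    if not has_final:
        # the annotated model stops before the expected terminal exon: its last
        # junction is internal, and the terminal acceptor is unknown
        final_acceptor_call = None
        final_donor_call = None

    # rescue scan downstream of the last annotated donor
    rescue = None
    rescue_credible = None
    if config.profile is not None and len(trans) >= 2:
        anchor = trans[-2] if has_final else trans[-1]
        coding_before = sum(len(e) for e in trans if e.end <= anchor.end)
        frame = trans[-1].phase if has_final else (3 - coding_before % 3) % 3
        rescue = rescue_terminal_exon(
            locus, anchor.end, frame, config.profile, config.rescue
        )
        rescue_credible = any(
            c.frame_ok and c.profile_matches == len(config.profile) for c in rescue
        )
        logger.info(
            "%s: rescue scan found %d candidates, credible=%s",
            species,
            len(rescue),
            rescue_credible,
        )

    # junction evidence for competing terminal exons
    splicing = None
    candidates = dict(config.extra_candidates)
    if has_final:
        candidates["exon7"] = trans[-1].start
    if junctions is not None and candidates:
        splicing = select_terminal_exon(junctions, candidates, config.min_reads)
        logger.info("%s: splicing call %s (support %s)", species, splicing.chosen, splicing.support)

    # CRD classification
    acceptors = [final_acceptor_call] if final_acceptor_call else []
    donors = [final_donor_call] if final_donor_call else []
    crd = None
    if protein is not None and config.motif_offset is not None:
        crd = build_crd_report(
            protein, config.motif_offset, acceptors, donors, config.expected_cys
        )
        status = crd.status
    else:
        status = call_functional_status(acceptors, donors, motif=None, cys_ok=None)

    annotation = None
    if (
        not has_final
        and rescue is not None
        and not rescue_credible
        and status is FunctionalStatus.INDETERMINATE
    ):
        annotation = DELETED_EXON

    verdict = _verdict_for(status, splicing)
    logger.info("%s: status %s -> verdict %s", species, status.value, verdict)
    return SpeciesReport(
        species=species,
        splice_calls=splice_calls,
        rescue=rescue,
        rescue_credible=rescue_credible,
        splicing=splicing,
        crd=crd,
        status=status,
        verdict=verdict,
        annotation=annotation,
    )


def run_panel(species_inputs, config: PipelineConfig = PipelineConfig()):
    """Run several species and summarize verdicts.

    ``species_inputs`` is a sequence of dicts with keys
    species, locus, model and optionally junctions, protein, config.
    Returns (reports, panel DataFrame, summary counts dict); row order follows
    input order and verdicts are independent of it.
    """
    inputs = list(species_inputs)
    if not inputs:
        raise ValueError("panel requires at least one species")
    labels = [d["species"] for d in inputs]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate species labels in panel")
    reports = []
    for d in inputs:
        reports.append(
            run_species(
                d["species"],
                d["locus"],
                d["model"],
                junctions=d.get("junctions"),
                protein=d.get("protein"),
                config=d.get("config", config),
            )
        )
    table = pd.DataFrame(
        {
            "species": [r.species for r in reports],
            "status": [r.status.value for r in reports],
            "verdict": [r.verdict for r in reports],
            "chosen_exon": [r.splicing.chosen if r.splicing else None for r in reports],
            "annotation": [r.annotation for r in reports],
        }
    )
    summary = {
        FUNCTIONAL: sum(r.verdict == FUNCTIONAL for r in reports),
        PSEUDOGENE: sum(r.verdict == PSEUDOGENE for r in reports),
        INDETERMINATE: sum(r.verdict == INDETERMINATE for r in reports),
    }
    return reports, table, summary


def tissue_specificity(
    table: pd.DataFrame, focal: str, threshold: float = 100.0
) -> SpecificityResult:
    """Fold-enrichment of the focal tissue over the highest other tissue.

    The ratio is focal abundance / max(other abundances); when no other tissue
    shows any signal but the focal one does, the ratio is reported as infinite.
    The pattern label carries the threshold used.
    """
    if "tissue" not in table.columns or "abundance" not in table.columns:
        raise ValueError("expression table must have 'tissue' and 'abundance' columns")
    if len(table) < 2:
        raise ValueError("need at least 2 tissues")
    if (table["abundance"] < 0).any():
        raise ValueError("abundances must be >= 0")
    rows = table.set_index("tissue")["abundance"]
    if focal not in rows.index:
        raise ValueError(f"focal tissue {focal!r} absent from table")
    focal_val = float(rows[focal])
    others = rows.drop(focal)
    max_other = float(others.max())
    if max_other == 0.0:
        if focal_val > 0:
            return SpecificityResult(focal, math.inf, True, RESTRICTED, threshold)
        return SpecificityResult(focal, 0.0, False, NOT_RESTRICTED, threshold)
    ratio = focal_val / max_other
    pattern = RESTRICTED if ratio >= threshold else NOT_RESTRICTED
    return SpecificityResult(focal, ratio, False, pattern, threshold)
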