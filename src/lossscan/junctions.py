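"""Intron-spanning junction evidence and terminal-exon splicing calls.

RNA-seq reads whose alignments are split across an exon-exon boundary identify
introns directly; tallying them at the acceptor positions of competing
terminal-exon models decides which exon is actually spliced (or that the final
intron is never removed at all).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

UNSPLICED = "UNSPLICED"
AMBIGUOUS = "AMBIGUOUS"


@dataclass(frozen=True)
class JunctionRecord:
    """One intron as evidenced by spanning reads: [donor_pos, acceptor_pos) is
    the 0-based half-open intron interval; ``reads`` is the spanning-read count."""

    donor_pos: int
    acceptor_pos: int
    reads: int

    def __post_init__(self) -> None:
        if self.donor_pos >= self.acceptor_pos:
            raise ValueError(
                f"donor_pos {self.donor_pos} must be < acceptor_pos {self.acceptor_pos}"
            )
        if self.reads < 0:
            raise ValueError(f"read count must be >= 0, got {self.reads}")


@dataclass(frozen=True)
class SplicingCall:
    """Outcome of comparing candidate terminal exons against junction evidence."""

    chosen: str  # exon identifier, UNSPLICED or AMBIGUOUS
    support: int
    alternatives: dict


def read_junctions(path) -> list:
    """Read a junction table (TSV: chrom, intron_start, intron_end, reads).

    Intron intervals are 0-based half-open. Duplicate intervals are summed.
    An empty file yields an empty list.
    """
    path = Path(path)
    if path.read_text().strip() == "":
        return []
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "intron_start", "intron_end", "reads"],
        comment="#",
    )
    agg = (
        df.groupby(["chrom", "intron_start", "intron_end"], sort=False)["reads"]
        .sum()
        .reset_index()
    )
    records = []
    for row in agg.itertuples(index=False):
        records.append(
            JunctionRecord(
                donor_pos=int(row.intron_start),
                acceptor_pos=int(row.intron_end),
                reads=int(row.reads),
            )
        )
    return records


def write_junctions(path, records, chrom: str = "locus") -> None:
    rows = [f"{chrom}\t{r.donor_pos}\t{r.acceptor_pos}\t{r.reads}" for r in records]
    Path(path).write_text("\n".join(rows) + ("\n" if rows else ""))


def select_terminal_exon(records, candidates: dict, min_reads: int = 2) -> SplicingCall:
    """Choose among competing terminal exons based on junction support.

    ``candidates`` maps exon identifier to its acceptor position; support for a
    candidate is the total reads of junctions whose acceptor matches. The
    winner must reach ``min_reads`` and strictly exceed the runner-up; if every
    candidate is below ``min_reads`` the locus is called UNSPLICED, and a tie
    at or above threshold is AMBIGUOUS.
    """
    if not candidates:
        raise ValueError("candidates must be a non-empty mapping")
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    support = {
        name: sum(r.reads for r in records if r.acceptor_pos == pos)
        for name, pos in candidates.items()
    }
    if all(v < min_reads for v in support.values()):
        return SplicingCall(chosen=UNSPLICED, support=0, alternatives=support)
    ordered = sorted(support.items(), key=lambda kv: -kv[1])
    top_name, top_reads = ordered[0]
    runner_up = ordered[1][1] if len(ordered) > 1 else 0
    if top_reads >= min_reads and top_reads > runner_up:
        return SplicingCall(chosen=top_name, support=top_reads, alternatives=support)
    return SplicingCall(chosen=AMBIGUOUS, support=top_reads, alternatives=support)
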