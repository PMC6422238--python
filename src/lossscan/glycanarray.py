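"""Glycan-array analysis: IUPAC-condensed parsing, epitope classes, spot stats.

Array structures follow the CFG condensed convention: the reducing-end residue
is rightmost, each non-root residue carries an anomeric letter and a
child-to-parent linkage (e.g. ``Galb1-4GlcNAc``), branches are parenthesized
before their parent (``Galb1-4(Fuca1-3)GlcNAc``), and a spacer/aglycone suffix
such as ``-Sp8`` may terminate the string (kept as metadata, never as a node).

Epitope classes mirror a galactose-receptor's reading of the array: LEWIS for
terminal Lewis-a/x trisaccharides, GALNAC/GAL for terminal GalNAc or Gal with
free 3- and 4-OH groups, OTHER for everything else. Precedence is
LEWIS > GALNAC > GAL > OTHER for glycans carrying several epitope types.
Sulfate/phosphate modifiers on a ring position count as substitution.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MONOSACCHARIDES = (
    "Neu5Ac",
    "Neu5Gc",
    "GlcNAc",
    "GalNAc",
    "ManNAc",
    "GlcA",
    "IdoA",
    "GlcN",
    "Gal",
    "Glc",
    "Man",
    "Fuc",
    "Xyl",
    "Rha",
    "Kdn",
    "Ara",
)

_RESIDUE_RE = re.compile("|".join(sorted(MONOSACCHARIDES, key=len, reverse=True)))
_LINKAGE_RE = re.compile(r"([ab?])([12?])-([1-9?])")
_MODIFIER_RE = re.compile(r"([1-9])(S|P)")
_SPACER_RE = re.compile(r"-(?:Sp|sp)[0-9A-Za-z]*$")


class GlycanParseError(ValueError):
    """Raised with the offending position when a structure string is malformed."""


class EpitopeClass(enum.Enum):
    LEWIS = "LEWIS"  # terminal Lewis-a / Lewis-x (red)
    GAL = "GAL"  # other terminal Gal, free 3-/4-OH (green)
    GALNAC = "GALNAC"  # terminal GalNAc, free 3-/4-OH (blue)
    OTHER = "OTHER"  # none of the above (black)


@dataclass(frozen=True)
class Linkage:
    """Anomeric configuration and child->parent attachment positions."""

    anomeric: str  # a | b | ?
    child_pos: str  # 1 | 2 | ?
    parent_pos: str  # 1-9 | ?


@dataclass
class GlycanNode:
    """One monosaccharide with sulfate/phosphate modifiers and child branches."""

    name: str
    modifiers: tuple = ()
    children: list = field(default_factory=list)  # list[(Linkage, GlycanNode)]

    def child_positions(self) -> set:
        return {link.parent_pos for link, _ in self.children}

    def modified_positions(self) -> set:
        return {pos for pos, _kind in self.modifiers}


@dataclass
class Glycan:
    """A rooted glycan tree; the root is the reducing-end residue."""

    root: GlycanNode
    spacer: str | None = None

    def nodes(self) -> list:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(child for _link, child in node.children)
        return out


# ---------------------------------------------------------------------------
# Parsing


def _tokenize(text: str) -> list:
    tokens = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "(":
            m = _MODIFIER_RE.match(text, i + 1)
            if m and text[m.end() : m.end() + 1] == ")":
                tokens.append(("MOD", (m.group(1), m.group(2)), i))
                i = m.end() + 1
                continue
            tokens.append(("LPAREN", None, i))
            i += 1
            continue
        if ch == ")":
            tokens.append(("RPAREN", None, i))
            i += 1
            continue
        m = _RESIDUE_RE.match(text, i)
        if m:
            tokens.append(("RES", m.group(0), i))
            i = m.end()
            lm = _LINKAGE_RE.match(text, i)
            if lm:
                tokens.append(
                    ("LINK", Linkage(lm.group(1), lm.group(2), lm.group(3)), i)
                )
                i = lm.end()
            elif i < len(text) and text[i] in "ab?":
                raise GlycanParseError(
                    f"position {i}: dangling or incomplete linkage after residue"
                )
            continue
        raise GlycanParseError(f"position {i}: unknown residue or symbol {ch!r}")
    return tokens


def _attach(parent: GlycanNode, link: Linkage, child: GlycanNode) -> None:
    if link.parent_pos != "?" and link.parent_pos in parent.child_positions():
        raise GlycanParseError(
            f"two children attached at position {link.parent_pos} of {parent.name}"
        )
    parent.children.append((link, child))


def _parse_chain(tokens: list, i: int, depth: int):
    """Parse one chain; returns (node, trailing_linkage_or_None, next_index).

    A trailing linkage is only legal inside parentheses, where it connects the
    branch to the parent residue that follows the closing paren.
    """
    pending = []  # (node, linkage) awaiting the next residue as parent
    mods = []
    while i < len(tokens):
        ttype, value, pos = tokens[i]
        if ttype == "LPAREN":
            child, link, i = _parse_chain(tokens, i + 1, depth + 1)
            if link is None:
                raise GlycanParseError(f"position {pos}: branch lacks a linkage")
            if i >= len(tokens) or tokens[i][0] != "RPAREN":
                raise GlycanParseError(f"position {pos}: unbalanced parenthesis")
            i += 1
            pending.append((child, link))
        elif ttype == "MOD":
            mods.append(value)
            i += 1
        elif ttype == "RES":
            node = GlycanNode(name=value, modifiers=tuple(mods))
            mods = []
            for child, link in pending:
                _attach(node, link, child)
            pending = []
            i += 1
            if i < len(tokens) and tokens[i][0] == "LINK":
                link = tokens[i][1]
                i += 1
                if i < len(tokens) and tokens[i][0] == "RPAREN":
                    if depth == 0:
                        raise GlycanParseError(
                            f"position {tokens[i][2]}: unbalanced parenthesis"
                        )
                    return node, link, i
                pending = [(node, link)]
            else:
                if depth > 0:
                    # root of a parenthesized branch must carry a linkage
                    if i < len(tokens) and tokens[i][0] == "RPAREN":
                        raise GlycanParseError(
                            f"position {tokens[i][2]}: branch lacks a linkage"
                        )
                return node, None, i
        elif ttype == "RPAREN":
            raise GlycanParseError(f"position {pos}: unexpected ')'")
        else:  # LINK without preceding residue
            raise GlycanParseError(f"position {pos}: linkage without residue")
    if pending or mods:
        raise GlycanParseError("dangling linkage or modifier at end of structure")
    raise GlycanParseError("empty structure")


def parse_iupac(text: str) -> Glycan:
    """Parse an IUPAC-condensed structure string into a Glycan tree."""
    s = text.strip().replace(" ", "")
    if not s:
        raise GlycanParseError("empty structure")
    spacer = None
    m = _SPACER_RE.search(s)
    if m:
        spacer = m.group(0)[1:]
        s = s[: m.start()]
    if not s:
        raise GlycanParseError("structure contains only a spacer")
    tokens = _tokenize(s)
    node, link, i = _parse_chain(tokens, 0, depth=0)
    if link is not None:
        raise GlycanParseError("dangling linkage at reducing end")
    if i != len(tokens):
        raise GlycanParseError(f"position {tokens[i][2]}: trailing tokens")
    return Glycan(root=node, spacer=spacer)


def serialize(glycan: Glycan) -> str:
    """Render a Glycan back to IUPAC-condensed text (inverse of parse_iupac up
    to branch ordering: the highest-position child is written as the backbone)."""

    def render(node: GlycanNode, link: Linkage | None) -> str:
        mods = "".join(f"({pos}{kind})" for pos, kind in node.modifiers)
        suffix = f"{link.anomeric}{link.child_pos}-{link.parent_pos}" if link else ""
        kids = sorted(node.children, key=lambda kv: kv[0].parent_pos)
        if kids:
            backbone_link, backbone = kids[-1]
            branches = "".join(
                f"({render(child, l)})" for l, child in kids[:-1]
            )
            return f"{render(backbone, backbone_link)}{branches}{mods}{node.name}{suffix}"
        return f"{mods}{node.name}{suffix}"

    text = render(glycan.root, None)
    if glycan.spacer:
        text += f"-{glycan.spacer}"
    return text


# ---------------------------------------------------------------------------
# Epitope classification

_RING_POSITIONS = frozenset("23456")


def _is_terminal(node: GlycanNode) -> bool:
    """Terminal = no residue children on ring positions 2-6 (an unknown
    attachment position is treated as potentially blocking)."""
    for link, _child in node.children:
        if link.parent_pos in _RING_POSITIONS or link.parent_pos == "?":
            return False
    return True


def _position_free(node: GlycanNode, pos: str) -> bool:
    if pos in node.child_positions() or "?" in node.child_positions():
        return False
    if pos in node.modified_positions():
        return False
    return True


def _has_lewis(node: GlycanNode) -> bool:
    """Lewis-x: Gal b1-4 (Fuc a1-3) GlcNAc; Lewis-a: Gal b1-3 (Fuc a1-4) GlcNAc,
    with the Gal terminal."""
    if node.name != "GlcNAc":
        return False
    gal = {l.parent_pos: c for l, c in node.children if c.name == "Gal" and l.anomeric == "b"}
    fuc = {l.parent_pos: c for l, c in node.children if c.name == "Fuc" and l.anomeric == "a"}
    for gal_pos, fuc_pos in (("4", "3"), ("3", "4")):  # Lewis-x, Lewis-a
        if gal_pos in gal and fuc_pos in fuc and _is_terminal(gal[gal_pos]):
            return True
    return False


def classify_epitope(glycan: Glycan) -> EpitopeClass:
    """Assign the single epitope class of a glycan.

    Precedence LEWIS > GALNAC > GAL > OTHER; GALNAC/GAL require a terminal
    residue with both the 3- and 4-OH unsubstituted (modifiers block an OH).
    """
    nodes = glycan.nodes()
    if any(_has_lewis(n) for n in nodes):
        return EpitopeClass.LEWIS
    for name, cls in (("GalNAc", EpitopeClass.GALNAC), ("Gal", EpitopeClass.GAL)):
        for n in nodes:
            if (
                n.name == name
                and _is_terminal(n)
                and _position_free(n, "3")
                and _position_free(n, "4")
            ):
                return cls
    return EpitopeClass.OTHER


# ---------------------------------------------------------------------------
# Spot statistics and ranking


@dataclass
class ArraySpot:
    """One array glycan with replicate RFUs and trimmed summary statistics."""

    glycan_id: int
    structure: str
    replicates: tuple
    mean: float | None = None
    sd: float | None = None
    epitope: EpitopeClass | None = None
    rank: int | None = None


def summarize_spot(replicates) -> tuple:
    """Trimmed mean and sample SD: exactly one maximal and one minimal value are
    excluded (one instance each under ties) before computing the statistics."""
    values = np.asarray(list(replicates), dtype=float)
    if values.size < 3:
        raise ValueError(f"need at least 3 replicate values, got {values.size}")
    trimmed = np.sort(values)[1:-1]
    mean = float(trimmed.mean())
    sd = float(trimmed.std(ddof=1)) if trimmed.size > 1 else 0.0
    return mean, sd


def make_spot(glycan_id: int, structure: str, replicates) -> ArraySpot:
    """Build a fully summarized, classified spot from raw replicates."""
    mean, sd = summarize_spot(replicates)
    epitope = classify_epitope(parse_iupac(structure))
    return ArraySpot(
        glycan_id=glycan_id,
        structure=structure,
        replicates=tuple(float(v) for v in replicates),
        mean=mean,
        sd=sd,
        epitope=epitope,
    )


def rank_array(spots, top_n: int = 100) -> list:
    """Rank spots by trimmed mean descending (ties by glycan id ascending) and
    return the top ``top_n`` with rank attached."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    ordered = sorted(spots, key=lambda s: (-s.mean, s.glycan_id))[:top_n]
    out = []
    for rank, s in enumerate(ordered, start=1):
        out.append(
            ArraySpot(
                glycan_id=s.glycan_id,
                structure=s.structure,
                replicates=s.replicates,
                mean=s.mean,
                sd=s.sd,
                epitope=s.epitope,
                rank=rank,
            )
        )
    return out


def read_array_table(path) -> list:
    """Read an array TSV (glycan_id, structure, rfu_1..rfu_n) into spots."""
    df = pd.read_csv(path, sep="\t")
    rfu_cols = [c for c in df.columns if c.startswith("rfu")]
    spots = []
    for row in df.itertuples(index=False):
        reps = [getattr(row, c) for c in rfu_cols]
        spots.append(make_spot(int(row.glycan_id), str(row.structure), reps))
    return spots


# Hand-curated reference panel: CFG-style structures with their expected
# epitope class under the rules above. Used to validate the classifier.
LABELED_REFERENCE_PANEL = (
    ("Galb1-4(Fuca1-3)GlcNAc-Sp0", EpitopeClass.LEWIS),
    ("Galb1-3(Fuca1-4)GlcNAc-Sp8", EpitopeClass.LEWIS),
    ("Galb1-4(Fuca1-3)GlcNAcb1-3Galb1-4Glc-Sp0", EpitopeClass.LEWIS),
    ("Galb1-3(Fuca1-4)GlcNAcb1-3Galb1-4Glc-Sp8", EpitopeClass.LEWIS),
    (
        "Galb1-4(Fuca1-3)GlcNAcb1-2Mana1-3(Galb1-4(Fuca1-3)GlcNAcb1-2Mana1-6)"
        "Manb1-4GlcNAcb1-4GlcNAc-Sp12",
        EpitopeClass.LEWIS,
    ),
    ("Galb1-4Glc-Sp8", EpitopeClass.GAL),
    ("Galb1-4GlcNAc-Sp0", EpitopeClass.GAL),
    ("Galb1-3GlcNAcb1-3Galb1-4Glc-Sp8", EpitopeClass.GAL),
    ("Gala1-3Galb1-4GlcNAc-Sp8", EpitopeClass.GAL),
    (
        "Galb1-4GlcNAcb1-2Mana1-3(Galb1-4GlcNAcb1-2Mana1-6)Manb1-4GlcNAcb1-4GlcNAc-Sp12",
        EpitopeClass.GAL,
    ),
    ("(6S)Galb1-4GlcNAc-Sp0", EpitopeClass.GAL),  # 6-sulfate leaves 3-/4-OH free
    ("Galb1-3GalNAc-Sp8", EpitopeClass.GAL),
    ("GalNAcb1-4GlcNAc-Sp0", EpitopeClass.GALNAC),
    ("GalNAca1-3Galb1-4Glc-Sp8", EpitopeClass.GALNAC),
    ("GalNAcb1-4GlcNAcb1-2Man-Sp8", EpitopeClass.GALNAC),
    ("GalNAcb1-3Gala1-4Galb1-4Glc-Sp8", EpitopeClass.GALNAC),
    ("GalNAca1-3(Fuca1-2)Galb1-4Glc-Sp0", EpitopeClass.GALNAC),
    ("Neu5Aca2-3Galb1-4GlcNAc-Sp8", EpitopeClass.OTHER),  # Gal 3-OH substituted
    ("Neu5Aca2-6Galb1-4GlcNAcb1-3Galb1-4Glc-Sp0", EpitopeClass.OTHER),
    (
        "Neu5Aca2-3Galb1-4(Fuca1-3)GlcNAcb1-3Galb1-4Glc-Sp8",  # sialyl-Lewis-x
        EpitopeClass.OTHER,
    ),
    ("Mana1-3(Mana1-6)Manb1-4GlcNAcb1-4GlcNAc-Sp12", EpitopeClass.OTHER),
    ("Mana1-2Mana1-3Man-Sp8", EpitopeClass.OTHER),
    ("GlcNAcb1-4GlcNAcb1-4GlcNAc-Sp8", EpitopeClass.OTHER),
    ("(3S)Galb1-4GlcNAc-Sp0", EpitopeClass.OTHER),  # sulfate blocks the 3-OH
    ("Fuca1-2Galb1-4Glc-Sp0", EpitopeClass.OTHER),  # Gal substituted at 2
)


def write_report(path, ranked) -> None:
    """Write a ranked report TSV (rank, glycan_id, structure, class, mean, sd)."""
    df = pd.DataFrame(
        {
            "rank": [s.rank for s in ranked],
            "glycan_id": [s.glycan_id for s in ranked],
            "structure": [s.structure for s in ranked],
            "class": [s.epitope.value for s in ranked],
            "mean": [s.mean for s in ranked],
            "sd": [s.sd for s in ranked],
        }
    )
    df.to_csv(path, sep="\t", index=False)
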