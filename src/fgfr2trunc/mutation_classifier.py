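"""Small-variant classification: hotspots, E18 splice-site and
proximal/distal E18-truncating mutations.

Hotspot residues default to the recurrent FGFR2 (Ser252, Cys382, Asn549,
Lys659) and FGFR3 (Arg248, Ser249, Tyr373, Lys650) missense positions.
Nonsense and frameshift mutations in the exon-18 coding range are split
into proximal (E768-Y783) versus distal (P784-T821) C-terminal truncations;
a frameshift is assigned by its first altered residue.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "Consequence",
    "MutationCategory",
    "MutationCall",
    "DEFAULT_HOTSPOTS",
    "PROXIMAL_RANGE",
    "DISTAL_RANGE",
    "parse_hgvs_p",
    "classify_mutation",
    "read_maf",
]

DEFAULT_HOTSPOTS: dict[str, frozenset[int]] = {
    "FGFR2": frozenset({252, 382, 549, 659}),
    "FGFR3": frozenset({248, 249, 373, 650}),
}

PROXIMAL_RANGE = (768, 783)  # inclusive amino-acid positions
DISTAL_RANGE = (784, 821)


class Consequence(str, enum.Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    SPLICE_SITE = "splice_site"
    OTHER = "other"


class MutationCategory(str, enum.Enum):
    HOTSPOT = "HOTSPOT"
    E18_SPLICE = "E18_SPLICE"
    PROXIMAL_TRUNCATING = "PROXIMAL_TRUNCATING"
    DISTAL_TRUNCATING = "DISTAL_TRUNCATING"
    OTHER = "OTHER"


@dataclass(frozen=True)
class MutationCall:
    gene: str
    protein_position: int | None
    ref_aa: str | None
    alt_aa: str | None
    consequence: Consequence
    category: MutationCategory
    sample_id: str | None = None


_AA3TO1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C", "Gln": "Q",
    "Glu": "E", "Gly": "G", "His": "H", "Ile": "I", "Leu": "L", "Lys": "K",
    "Met": "M", "Phe": "F", "Pro": "P", "Ser": "S", "Thr": "T", "Trp": "W",
    "Tyr": "Y", "Val": "V", "Ter": "*",
}

_HGVS_RE = re.compile(
    r"^(?:p\.)?\(?([A-Za-z*]{1,3})(\d+)([A-Za-z*]{0,3}?)(fs.*|\*|ext.*)?\)?$"
)


def _norm_aa(token: str) -> str | None:
    if not token:
        return None
    if token in _AA3TO1:
        return _AA3TO1[token]
    if len(token) == 1:
        return token.upper()
    return _AA3TO1.get(token.capitalize(), token)


def parse_hgvs_p(change: str) -> tuple[str | None, int, str | None, bool]:
    """Parse an HGVS-p style protein change.

    Accepts "p.N549K", "N549K", "p.Asn549Lys", "p.E769*", "S799fs" and the
    like, case-tolerant on the "p." prefix.  Returns
    ``(ref_aa, position, alt_aa, is_frameshift)`` with one-letter codes and
    "*" for a stop.
    """
    m = _HGVS_RE.match(change.strip())
    if not m:
        raise ValueError(f"cannot parse protein change {change!r}")
    ref, pos, alt, tail = m.groups()
    frameshift = bool(tail and tail.startswith("fs")) or bool(alt and alt.lower().startswith("fs"))
    if alt and alt.lower().startswith("fs"):
        alt = ""
    alt_aa = _norm_aa(alt) if alt else (_norm_aa(tail) if tail == "*" else None)
    return _norm_aa(ref), int(pos), alt_aa, frameshift


def _infer_consequence(ref: str | None, alt: str | None, frameshift: bool) -> Consequence:
    if frameshift:
        return Consequence.FRAMESHIFT
    if alt == "*":
        return Consequence.NONSENSE
    if ref and alt and ref != "*":
        return Consequence.MISSENSE
    return Consequence.OTHER


def classify_mutation(
    gene: str,
    protein_change: str | None = None,
    *,
    protein_position: int | None = None,
    ref_aa: str | None = None,
    alt_aa: str | None = None,
    consequence: Consequence | str | None = None,
    is_e18_splice_acceptor: bool = False,
    hotspots: dict[str, frozenset[int]] | None = None,
    sample_id: str | None = None,
) -> MutationCall:
    """Classify a small variant given either an HGVS-p string or an
    explicit (position, ref, alt) triplet; both routes are equivalent.

    E18 splice-acceptor variants are flagged by the caller (the acceptor
    window, by default the two intronic bases preceding E18 plus its first
    exonic base, is resolved at annotation time from genomic coordinates).
    """
    if gene is None or gene == "":
        raise ValueError("unknown gene")
    hotspots = DEFAULT_HOTSPOTS if hotspots is None else hotspots

    frameshift = False
    if protein_change is not None:
        ref_aa, protein_position, alt_aa, frameshift = parse_hgvs_p(protein_change)
    if consequence is None:
        csq = Consequence.SPLICE_SITE if is_e18_splice_acceptor else _infer_consequence(
            ref_aa, alt_aa, frameshift
        )
    else:
        csq = Consequence(consequence)

    category = MutationCategory.OTHER
    if csq is Consequence.SPLICE_SITE and is_e18_splice_acceptor:
        category = MutationCategory.E18_SPLICE
    elif csq is Consequence.MISSENSE and protein_position in hotspots.get(gene, frozenset()):
        category = MutationCategory.HOTSPOT
    elif csq in (Consequence.NONSENSE, Consequence.FRAMESHIFT) and protein_position is not None:
        if PROXIMAL_RANGE[0] <= protein_position <= PROXIMAL_RANGE[1]:
            category = MutationCategory.PROXIMAL_TRUNCATING
        elif DISTAL_RANGE[0] <= protein_position <= DISTAL_RANGE[1]:
            category = MutationCategory.DISTAL_TRUNCATING
    return MutationCall(gene, protein_position, ref_aa, alt_aa, csq, category, sample_id)


def read_maf(path) -> list[MutationCall]:
    """Read a MAF-like TSV with columns sample_id, gene, protein_change,
    consequence (and optional is_e18_splice_acceptor)."""
    df = pd.read_csv(path, sep="\t")
    calls = []
    for r in df.itertuples(index=False):
        splice = bool(getattr(r, "is_e18_splice_acceptor", False))
        change = getattr(r, "protein_change", None)
        change = None if (change is None or pd.isna(change) or change == "") else str(change)
        csq = getattr(r, "consequence", None)
        csq = None if (csq is None or pd.isna(csq)) else str(csq)
        calls.append(
            classify_mutation(
                str(r.gene),
                change,
                consequence=csq,
                is_e18_splice_acceptor=splice,
                sample_id=str(r.sample_id),
            )
        )
    return calls
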