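"""Rearrangement typing, allele frequencies and insertion-site utilities.

A breakpoint pair is assigned exactly one of six rearrangement (RE) types:

IN_FRAME_FUSION   both sides in coding genes with a splice-phase-compatible
                  (or exonic in-frame) junction
FRAME_UNKNOWN     coding partner but the fused reading frame is unpredictable
INTERGENIC_SPACE  the partner side falls in non-coding intergenic space
OUT_OF_STRAND     the downstream partner is supported by antisense reads
INTERNAL          both breakends lie within the gene of interest
UNRESOLVED        antisense support on the upstream side, or a single breakend

Rules are evaluated in the fixed order UNRESOLVED -> INTERNAL ->
INTERGENIC_SPACE -> OUT_OF_STRAND -> frame evaluation.  A sample-level
exon-18-truncating call additionally requires the gene-of-interest breakend
in the last intron or last exon and an RE allele frequency strictly > 0.15.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .gene_model import (
    ANTISENSE,
    SENSE,
    ExonPhase,
    GeneModel,
    GeneSet,
    GenomicBreakend,
    NonCodingModelError,
    annotate_breakend,
    compute_exon_phases,
)

__all__ = [
    "REType",
    "RearrangementCall",
    "InsertionRecord",
    "select_backbone",
    "classify_re",
    "compute_allele_frequency",
    "normalize_clonality",
    "call_insertion_hits",
    "sliding_window_density",
    "read_bedpe",
    "calls_to_frame",
    "E18_AF_THRESHOLD",
    "CLONALITY_HIT_THRESHOLD",
]

E18_AF_THRESHOLD = 0.15  # strict: allele frequency must exceed this
CLONALITY_HIT_THRESHOLD = 0.25  # inclusive: relative clonality >= 0.25 is a hit


class REType(str, enum.Enum):
    IN_FRAME_FUSION = "IN_FRAME_FUSION"
    FRAME_UNKNOWN = "FRAME_UNKNOWN"
    INTERGENIC_SPACE = "INTERGENIC_SPACE"
    OUT_OF_STRAND = "OUT_OF_STRAND"
    INTERNAL = "INTERNAL"
    UNRESOLVED = "UNRESOLVED"


#: RE types counted as E18-truncating evidence (unresolved REs are excluded)
E18_EVIDENCE_TYPES = frozenset(
    {
        REType.IN_FRAME_FUSION,
        REType.FRAME_UNKNOWN,
        REType.INTERGENIC_SPACE,
        REType.OUT_OF_STRAND,
        REType.INTERNAL,
    }
)


@dataclass(frozen=True)
class RearrangementCall:
    breakend_a: GenomicBreakend
    breakend_b: GenomicBreakend | None
    re_type: REType
    backbone_gene: str | None = None
    junction_ploidy: float = float("nan")
    allele_frequency: float = float("nan")
    e18_truncating: bool = False
    sample_id: str | None = None


@dataclass(frozen=True)
class InsertionRecord:
    position: int
    ligation_score: float
    relative_clonality: float
    orientation: str


def select_backbone(gene_a: GeneModel, gene_b: GeneModel) -> str:
    """Pick the classification backbone: the partner encoding the longer
    protein; a sole coding partner wins; ties break lexicographically."""
    if not gene_a.coding and not gene_b.coding:
        raise NonCodingModelError("both partners non-coding: no backbone")
    if gene_a.coding and not gene_b.coding:
        return gene_a.gene_id
    if gene_b.coding and not gene_a.coding:
        return gene_b.gene_id
    la, lb = gene_a.protein_length or 0, gene_b.protein_length or 0
    if la != lb:
        return gene_a.gene_id if la > lb else gene_b.gene_id
    return min(gene_a.gene_id, gene_b.gene_id)


def _phase_at_exonic_break(
    model: GeneModel, phases: dict[int, ExonPhase], exon_index: int, position: int
) -> int | None:
    """Codon phase immediately at an exonic break position.

    Returns None when the break lies in the exon's untranslated part (or the
    exon carries no CDS), which makes the fused frame unpredictable.
    """
    cds = model.cds_in_exon(exon_index)
    if cds is None or exon_index not in phases:
        return None
    cs, ce = cds
    if not (cs <= position < ce):
        return None
    if model.strand == "+":
        offset = position - cs
    else:
        offset = ce - position - 1
    return (phases[exon_index].start_phase + offset) % 3


def _junction_phases(
    upstream: GenomicBreakend,
    downstream: GenomicBreakend,
    models: GeneSet,
) -> tuple[int | None, int | None]:
    """Phase offered by the upstream side and expected by the downstream
    side of the junction; None marks an unpredictable side."""
    up_model = models[upstream.gene_id]
    dn_model = models[downstream.gene_id]
    up_phases = {p.exon_index: p for p in compute_exon_phases(up_model)}
    dn_phases = {p.exon_index: p for p in compute_exon_phases(dn_model)}

    if upstream.feature == "intron":
        k = upstream.index
        up = up_phases[k].end_phase if k in up_phases else None
    else:
        up = _phase_at_exonic_break(up_model, up_phases, upstream.index, upstream.position)

    if downstream.feature == "intron":
        j = downstream.index + 1
        dn = dn_phases[j].start_phase if j in dn_phases else None
    else:
        dn = _phase_at_exonic_break(dn_model, dn_phases, downstream.index, downstream.position)
    return up, dn


def classify_re(
    breakend_a: GenomicBreakend,
    breakend_b: GenomicBreakend | None,
    models: GeneSet,
    *,
    gene_of_interest: str = "FGFR2",
    require_codon_complete: bool = False,
) -> RearrangementCall:
    """Assign exactly one RE type to an annotated breakpoint pair.

    ``breakend_a`` is normalised to the gene-of-interest (upstream) side, so
    swapping the input order yields the identical call.  With
    ``require_codon_complete`` the intronic in-frame test additionally
    requires both junction-adjacent exons to contain whole codons (the
    stricter reading of a "complete reading frame").
    """
    # normalise: the side inside the gene of interest is breakend_a
    if breakend_b is not None:
        a_in = breakend_a.gene_id == gene_of_interest
        b_in = breakend_b.gene_id == gene_of_interest
        if b_in and not a_in:
            breakend_a, breakend_b = breakend_b, breakend_a

    def call(re_type: REType, backbone: str | None) -> RearrangementCall:
        return RearrangementCall(breakend_a, breakend_b, re_type, backbone)

    # (6) unresolved: antisense-supported upstream side or single breakend
    single = breakend_b is None or (
        breakend_a.chromosome == breakend_b.chromosome
        and breakend_a.position == breakend_b.position
    )
    if single or breakend_a.read_orientation == ANTISENSE:
        return call(REType.UNRESOLVED, None)

    # (5) internal: both breakends within the gene of interest
    if breakend_a.gene_id == gene_of_interest and breakend_b.gene_id == gene_of_interest:
        return call(REType.INTERNAL, gene_of_interest)

    # (3) intergenic space: partner in non-coding space (incl. non-coding genes)
    partner_model = None if breakend_b.is_intergenic else models[breakend_b.gene_id]
    if partner_model is None or not partner_model.coding:
        return call(REType.INTERGENIC_SPACE, breakend_a.gene_id)

    backbone = select_backbone(models[breakend_a.gene_id], partner_model)

    # (4) out of strand: sense-supported upstream, antisense downstream partner
    if breakend_b.read_orientation == ANTISENSE:
        return call(REType.OUT_OF_STRAND, backbone)

    # (1)/(2) frame evaluation
    up, dn = _junction_phases(breakend_a, breakend_b, models)
    if up is None or dn is None or up != dn:
        return call(REType.FRAME_UNKNOWN, backbone)
    if require_codon_complete and breakend_a.feature == "intron" and breakend_b.feature == "intron":
        up_model = models[breakend_a.gene_id]
        dn_model = models[breakend_b.gene_id]
        up_cds = up_model.cds_in_exon(breakend_a.index)
        dn_cds = dn_model.cds_in_exon(breakend_b.index + 1)
        for cds in (up_cds, dn_cds):
            if cds is None or (cds[1] - cds[0]) % 3 != 0:
                return call(REType.FRAME_UNKNOWN, backbone)
    return call(REType.IN_FRAME_FUSION, backbone)


def compute_allele_frequency(
    call: RearrangementCall,
    gene_cn: float,
    *,
    junction_ploidy: float | None = None,
    gene_of_interest_model: GeneModel | None = None,
    threshold: float = E18_AF_THRESHOLD,
) -> RearrangementCall:
    """Attach the RE allele frequency and the E18-truncating flag.

    allele_frequency = junction_ploidy / gene_cn, clamped to [0, 1].  The
    call is E18-truncating iff the gene-of-interest breakend lies in the
    last intron or last exon, the frequency strictly exceeds ``threshold``
    and the RE type is not UNRESOLVED.
    """
    if gene_cn <= 0:
        raise ValueError(f"gene copy number must be positive, got {gene_cn}")
    jp = call.junction_ploidy if junction_ploidy is None else junction_ploidy
    if not np.isfinite(jp):
        raise ValueError("junction ploidy is required to compute allele frequency")
    af = min(max(jp / gene_cn, 0.0), 1.0)
    truncating = False
    if call.re_type in E18_EVIDENCE_TYPES and af > threshold:
        be = call.breakend_a
        if gene_of_interest_model is not None and be.gene_id == gene_of_interest_model.gene_id:
            n = gene_of_interest_model.n_exons
            truncating = (be.feature == "intron" and be.index == n - 1) or (
                be.feature == "exon" and be.index == n
            )
    return replace(call, junction_ploidy=jp, allele_frequency=af, e18_truncating=truncating)


def normalize_clonality(ligation_scores: list[float]) -> list[float]:
    """Relative clonality: each ligation score over the sample maximum,
    giving values in [0, 1] with the top insertion at exactly 1."""
    scores = np.asarray(ligation_scores, dtype=float)
    if scores.size == 0 or np.any(scores < 0):
        raise ValueError("ligation scores must be a non-empty non-negative list")
    top = scores.max()
    if top <= 0:
        raise ValueError("all ligation scores are zero; clonality undefined")
    return list(scores / top)


def call_insertion_hits(
    ligation_scores: list[float], threshold: float = CLONALITY_HIT_THRESHOLD
) -> list[bool]:
    """Gene-level insertion hits: relative clonality >= 0.25 (inclusive)."""
    return [c >= threshold for c in normalize_clonality(ligation_scores)]


def sliding_window_density(
    positions: list[int],
    window: int = 500,
    *,
    start: int | None = None,
    end: int | None = None,
) -> tuple[np.ndarray, int]:
    """Breakpoint/insertion density in a centred sliding window of
    ``window`` bp, stepped 1 bp.

    Returns ``(track, offset)`` with ``track[i]`` the number of positions
    within the window centred at genomic coordinate ``offset + i``.  Summing
    the track at non-overlapping window-spaced centres conserves the total
    number of positions.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    pos = np.sort(np.asarray(positions, dtype=int))
    if pos.size == 0:
        lo = start if start is not None else 0
        hi = end if end is not None else lo + 1
        return np.zeros(max(hi - lo, 1), dtype=int), lo
    half_lo = (window - 1) // 2
    half_hi = window - 1 - half_lo
    lo = start if start is not None else int(pos[0]) - window
    hi = end if end is not None else int(pos[-1]) + window + 1
    centers = np.arange(lo, hi)
    left = np.searchsorted(pos, centers - half_lo, side="left")
    right = np.searchsorted(pos, centers + half_hi, side="right")
    return (right - left).astype(int), lo


def read_bedpe(path, models: GeneSet, *, gene_of_interest: str = "FGFR2") -> list[tuple]:
    """Read breakend pairs from a headered BEDPE-style TSV (0-based starts).

    Strand columns are converted to read orientation relative to the
    containing gene at load time (a read on a gene's coding strand is sense);
    intergenic breakends keep sense orientation by convention.  Returns
    ``(sample_id, breakend_a, breakend_b, junction_ploidy)`` tuples with the
    gene-of-interest side first.
    """
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        pairs = []
        for chrom, pos, strand in (
            (row.chrom1, int(row.start1), row.strand1),
            (row.chrom2, int(row.start2), row.strand2),
        ):
            genes = models.genes_at(chrom, pos)
            if genes:
                orient = SENSE if strand == genes[0].strand else ANTISENSE
            else:
                orient = SENSE
            pairs.append(annotate_breakend(chrom, pos, orient, models))
        a, b = pairs
        if b.gene_id == gene_of_interest and a.gene_id != gene_of_interest:
            a, b = b, a
        ploidy = float(getattr(row, "junction_ploidy", float("nan")))
        out.append((str(row.sample_id), a, b, ploidy))
    return out


def calls_to_frame(calls: list[RearrangementCall]) -> pd.DataFrame:
    """Tabulate RearrangementCalls with all fields, one row per call."""
    rows = []
    for c in calls:
        rows.append(
            {
                "sample_id": c.sample_id,
                "chrom_a": c.breakend_a.chromosome,
                "pos_a": c.breakend_a.position,
                "context_a": "/".join(map(str, c.breakend_a.context)),
                "orientation_a": c.breakend_a.read_orientation,
                "chrom_b": c.breakend_b.chromosome if c.breakend_b else None,
                "pos_b": c.breakend_b.position if c.breakend_b else None,
                "context_b": "/".join(map(str, c.breakend_b.context)) if c.breakend_b else None,
                "orientation_b": c.breakend_b.read_orientation if c.breakend_b else None,
                "re_type": c.re_type.value,
                "backbone_gene": c.backbone_gene,
                "junction_ploidy": c.junction_ploidy,
                "allele_frequency": c.allele_frequency,
                "e18_truncating": c.e18_truncating,
            }
        )
    return pd.DataFrame(rows)
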