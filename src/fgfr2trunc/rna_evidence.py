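"""RNA-level evidence of exon-18 truncation.

Quantifies how often the gene's penultimate exon (E17) splices to the
canonical last exon (C1) versus alternative last exons (C2/C3/C4),
rearrangement partners, intergenic pseudoexons or an inserted transposon;
plus E18 expression loss, chimeric-read filtering and the composite FGFR
expression biomarker.

Alternative last exons C3/C4 encode dysfunctional C termini and count as
truncation-like acceptors; C2 overlaps the proximal canonical C terminus
and is treated as full-length-like.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "JunctionTable",
    "ChimericRead",
    "UNDEFINED_USAGE",
    "acceptor_usage",
    "call_e18_truncated_rna",
    "filter_chimeric_reads",
    "e18_loss",
    "sb_splice_ratio",
    "composite_fgfr_expression",
    "usage_outlier_z",
    "ccle_fusion_filter",
    "read_star_sj",
    "E17_JUNCTION_THRESHOLD",
    "MIN_SPANNING_READS",
    "TRUNCATING_ACCEPTOR_CLASSES",
]

E17_JUNCTION_THRESHOLD = 0.15   # strict >
MIN_SPANNING_READS = 2          # strict >: keep breakpoints with count > 2
COMPOSITE_HIGH_THRESHOLD = 3.0  # strict >
OUTLIER_P = 0.01                # one-sided upper-tail normal

#: acceptor classes counted as RE-derived truncation evidence by default;
#: C3/C4 usage is truncation-like but quantified separately (configurable)
TRUNCATING_ACCEPTOR_CLASSES = frozenset({"partner", "IGR", "SB"})

#: sentinel for usage that cannot be computed (zero donor junction reads)
UNDEFINED_USAGE = None


@dataclass(frozen=True)
class JunctionTable:
    """Donor->acceptor unique junction read counts for one sample.

    Acceptor labels: "E18-C1".."E18-C4", "partner:<gene>", "IGR", "SB".
    """

    sample_id: str
    entries: tuple[tuple[str, str, int], ...]  # (donor, acceptor, unique reads)

    def counts_from(self, donor: str) -> dict[str, int]:
        out: dict[str, int] = {}
        for d, acc, n in self.entries:
            if d == donor:
                if n < 0 or n != int(n):
                    raise ValueError("junction read counts must be non-negative integers")
                if acc in out:
                    raise ValueError(f"duplicate acceptor {acc!r} for donor {donor!r}")
                out[acc] = int(n)
        return out


@dataclass(frozen=True)
class ChimericRead:
    breakpoint: tuple[str, int]
    alignment_count: int = 1
    duplicate_flag: bool = False
    partner_class: str = "gene"  # gene|intergenic|antisense|mitochondrial|immunoglobulin|HLA


def acceptor_usage(table: JunctionTable, donor: str = "E17"):
    """Per-acceptor usage fractions of a donor exon's junction reads.

    Fractions sum to 1 over observed acceptors.  Zero total junction reads
    gives the undefined-usage marker (None), never 0.
    """
    counts = table.counts_from(donor)
    total = sum(counts.values())
    if total == 0:
        return UNDEFINED_USAGE
    return {acc: n / total for acc, n in counts.items()}


def _acceptor_class(acceptor: str) -> str:
    if acceptor.startswith("partner"):
        return "partner"
    if acceptor in ("IGR", "IGR-pseudoexon"):
        return "IGR"
    if acceptor == "SB":
        return "SB"
    return acceptor  # E18-C1..C4


def call_e18_truncated_rna(
    usage: dict[str, float] | None,
    threshold: float = E17_JUNCTION_THRESHOLD,
    *,
    evidence_classes: frozenset[str] = TRUNCATING_ACCEPTOR_CLASSES,
) -> bool:
    """RNA-level E18-truncation call: summed donor-junction usage of the
    configured evidence acceptor classes strictly exceeds ``threshold``.

    The default evidence classes are the RE-derived acceptors (fusion
    partner, intergenic pseudoexon, transposon); add "E18-C3"/"E18-C4" to
    count alternative-last-exon usage as well.  Undefined usage is False.
    """
    if usage is UNDEFINED_USAGE:
        return False
    frac = sum(f for acc, f in usage.items() if _acceptor_class(acc) in evidence_classes)
    return frac > threshold


def filter_chimeric_reads(
    reads: list[ChimericRead], min_count: int = MIN_SPANNING_READS + 1
) -> set[tuple[str, int]]:
    """Chimeric-read filtering: discard multi-aligned reads, PCR duplicates
    and mitochondrial/immunoglobulin/HLA partners, then keep breakpoints
    whose surviving spanning-read count exceeds ``min_count - 1``."""
    surviving: dict[tuple[str, int], int] = {}
    for r in reads:
        if r.alignment_count > 1 or r.duplicate_flag:
            continue
        if r.partner_class in ("mitochondrial", "immunoglobulin", "HLA"):
            continue
        surviving[r.breakpoint] = surviving.get(r.breakpoint, 0) + 1
    return {bp for bp, n in surviving.items() if n >= min_count}


def e18_loss(
    exon_expression: pd.Series,
    normal_reference: float,
    *,
    n_exons: int = 18,
) -> bool:
    """E18 expression-loss test: E18 normalised to the median of E1-E17 is
    below the minimum normalised E18 seen in normal tissue."""
    e17 = exon_expression[[f"E{i}" for i in range(1, n_exons)]].astype(float)
    med = float(e17.median())
    if med <= 0:
        raise ValueError("median E1-E17 expression must be positive")
    normalized_e18 = float(exon_expression[f"E{n_exons}"]) / med
    return normalized_e18 < normal_reference


def normal_e18_reference(matrix: pd.DataFrame, normal_flags: pd.Series, *, n_exons: int = 18) -> float:
    """Minimum normalised E18 expression across normal samples."""
    normals = matrix.loc[normal_flags.astype(bool)]
    if normals.empty:
        raise ValueError("at least one normal sample is required")
    med = normals[[f"E{i}" for i in range(1, n_exons)]].median(axis=1)
    return float((normals[f"E{n_exons}"] / med).min())


def sb_splice_ratio(e17_to_sb: int, e17_to_e18: int) -> tuple[float, float]:
    """Transposon splice capture: (SB/E18 ratio, SB/(SB+E18) fraction).

    A zero E18 count gives an infinite ratio marker with fraction 1.
    """
    total = e17_to_sb + e17_to_e18
    if total <= 0:
        raise ValueError("at least one junction read is required")
    fraction = e17_to_sb / total
    ratio = math.inf if e17_to_e18 == 0 else e17_to_sb / e17_to_e18
    return ratio, fraction


def composite_fgfr_expression(
    matrix: pd.DataFrame,
    *,
    receptors: tuple[str, ...] = ("FGFR1", "FGFR2", "FGFR3", "FGFR4"),
    pseudocount: float = 0.01,
    high_threshold: float = COMPOSITE_HIGH_THRESHOLD,
) -> pd.DataFrame:
    """Composite FGFR expression: each receptor normalised by its cohort
    geometric mean (linear scale, pseudocount on zeros), then summed.

    Returns a frame with columns ``score`` and ``high`` (score > 3).  A
    sample expressing every receptor exactly at its cohort geometric mean
    scores ``len(receptors)``.
    """
    if len(matrix) < 2:
        raise ValueError("composite expression needs >= 2 samples")
    expr = matrix[list(receptors)].astype(float) + pseudocount
    if (expr <= 0).any().any():
        raise ValueError("expression values must be non-negative")
    geomean = np.exp(np.log(expr).mean(axis=0))
    score = (expr / geomean).sum(axis=1)
    return pd.DataFrame({"score": score, "high": score > high_threshold})


def usage_outlier_z(usage_values: pd.Series, *, p_cutoff: float = OUTLIER_P) -> pd.Series:
    """Cohort-level high-usage outliers by Z-score normalisation.

    Flags samples whose one-sided upper-tail normal p (of the Z-scored
    usage) is below ``p_cutoff``.  A constant usage vector has undefined
    Z-scores: nothing is flagged and a warning is emitted.
    """
    x = usage_values.astype(float).dropna()
    if len(x) < 3:
        raise ValueError("usage outlier test needs >= 3 samples with defined usage")
    sd = x.std(ddof=1)
    flags = pd.Series(False, index=usage_values.index)
    if sd == 0:
        warnings.warn("constant usage vector: Z-scores undefined, no outliers flagged")
        return flags
    z = (x - x.mean()) / sd
    p = stats.norm.sf(z)
    flags.loc[x.index] = p < p_cutoff
    return flags


def ccle_fusion_filter(
    ffpm: float, spanning_fragments: int, partner_rpkm: float
) -> bool:
    """Cell-line fusion-call filter: FFPM > 0.1, spanning fragments >= 5
    and partner expression RPKM >= 1 must all hold."""
    return ffpm > 0.1 and spanning_fragments >= 5 and partner_rpkm >= 1


def read_star_sj(path, sample_id: str, acceptor_map: dict[int, str], donor_map: dict[int, str]) -> JunctionTable:
    """Read a STAR SJ.out.tab-dialect junction file into a JunctionTable.

    Columns: chrom, intron start (1-based), intron end, strand code, motif,
    annotated, unique reads, multi reads, overhang.  ``donor_map`` and
    ``acceptor_map`` translate junction boundary coordinates to exon labels;
    unmapped junctions are ignored.  Only uniquely mapped reads count.
    """
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "strand", "motif", "annotated",
               "unique_reads", "multi_reads", "overhang"],
    )
    entries = []
    for r in df.itertuples(index=False):
        donor = donor_map.get(int(r.start) - 1)
        acceptor = acceptor_map.get(int(r.end))
        if donor is not None and acceptor is not None:
            entries.append((donor, acceptor, int(r.unique_reads)))
    return JunctionTable(sample_id, tuple(entries))
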