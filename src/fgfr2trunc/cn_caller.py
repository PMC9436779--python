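"""Full-length and E1-E17 partial amplification calling.

Four rule sets mirror the different data modalities:

WGS    absolute copy number; amplification when gene CN > 5; partial
       E1-E17 amplification when a segment breakpoint lies in the last
       intron, CN(E1-E17) > 5 and CN(E1-E17) - CN(E18) > 2.
TCGA   log2(CN/2) segment values; GISTIC-style > 0.3 on E1-E17 and a
       segment-value difference > 0.3 across the last intron.
CCLE   log2(CN/2) >= 2 is an amplification (single gene-level value).
PANEL  per-exon target CNs; amplified target means CN >= 4 + sample median
       ploidy; gene amplification when >= 80% of all targets are amplified;
       partial when >= 80% of E1-E17 targets are amplified but the E18
       target sits below the amplification threshold.

E1-E17 and E18 summaries over segments are length-weighted means of the
segments overlapping the respective exon intervals.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gene_model import GeneModel

__all__ = [
    "Scale",
    "AmpStatus",
    "CopyNumberProfile",
    "AmplificationCall",
    "call_amp_wgs",
    "call_amp_tcga",
    "call_amp_ccle",
    "call_amp_panel",
    "read_seg",
    "read_exon_targets",
    "WGS_AMP_CN",
    "WGS_PARTIAL_DIFF",
    "TCGA_AMP_LOG2",
    "CCLE_AMP_LOG2",
    "PANEL_TARGET_FRACTION",
    "PANEL_CN_OVER_PLOIDY",
]

WGS_AMP_CN = 5.0          # strict >
WGS_PARTIAL_DIFF = 2.0    # strict >
TCGA_AMP_LOG2 = 0.3       # strict >
CCLE_AMP_LOG2 = 2.0       # inclusive >=
PANEL_TARGET_FRACTION = 0.8   # inclusive >=
PANEL_CN_OVER_PLOIDY = 4.0    # amplified target: CN >= 4 + median ploidy


class Scale(str, enum.Enum):
    ABSOLUTE_CN = "absolute_cn"
    LOG2_RATIO = "log2_ratio"


class AmpStatus(str, enum.Enum):
    NONE = "NONE"
    FULL_LENGTH_AMP = "FULL_LENGTH_AMP"
    PARTIAL_AMP_E1_E17 = "PARTIAL_AMP_E1_E17"


@dataclass(frozen=True)
class CopyNumberProfile:
    """Copy-number state of one sample over the gene of interest.

    ``segments`` are (start, end, value) with 0-based half-open genomic
    intervals, non-overlapping; ``exon_target_cn`` are per-exon target copy
    numbers in transcript order (E1..En) for panel data.
    """

    sample_id: str
    segments: tuple[tuple[int, int, float], ...] = ()
    exon_target_cn: tuple[float, ...] | None = None
    median_ploidy: float = 2.0
    scale: Scale = Scale.ABSOLUTE_CN


@dataclass(frozen=True)
class AmplificationCall:
    status: AmpStatus
    rule_set: str
    cn_e1_e17: float
    cn_e18: float
    sample_id: str | None = None


def _weighted_mean_over(segments, intervals) -> float:
    """Length-weighted mean segment value over a set of genomic intervals."""
    total_w = 0.0
    total = 0.0
    for lo, hi in intervals:
        for s, e, v in segments:
            w = min(hi, e) - max(lo, s)
            if w > 0:
                total_w += w
                total += w * v
    return total / total_w if total_w > 0 else float("nan")


def _last_intron(gene: GeneModel) -> tuple[int, int]:
    a = gene.exons[-2]
    b = gene.exons[-1]
    if gene.strand == "+":
        return (a[1], b[0])
    return (b[1], a[0])


def _break_in_last_intron(profile: CopyNumberProfile, gene: GeneModel, tol: int = 1) -> bool:
    """A segment boundary inside the last intron (+-1 bp dialect guard)."""
    lo, hi = _last_intron(gene)
    for s, e, _ in profile.segments:
        for bp in (s, e):
            if lo - tol <= bp <= hi + tol:
                return True
    return False


def _summaries(profile: CopyNumberProfile, gene: GeneModel) -> tuple[float, float]:
    e1_e17 = [tuple(sorted(x)) for x in gene.exons[:-1]]
    e18 = [tuple(sorted(gene.exons[-1]))]
    segs = profile.segments
    return _weighted_mean_over(segs, e1_e17), _weighted_mean_over(segs, e18)


def call_amp_wgs(profile: CopyNumberProfile, gene: GeneModel) -> AmplificationCall:
    """Absolute-CN rules: partial iff break in last intron, CN(E1-E17) > 5
    and CN(E1-E17) - CN(E18) > 2; else full-length iff gene CN > 5."""
    if profile.scale is not Scale.ABSOLUTE_CN:
        raise ValueError("WGS rule set requires absolute copy numbers")
    cn17, cn18 = _summaries(profile, gene)
    if (
        _break_in_last_intron(profile, gene)
        and cn17 > WGS_AMP_CN
        and cn17 - cn18 > WGS_PARTIAL_DIFF
    ):
        status = AmpStatus.PARTIAL_AMP_E1_E17
    else:
        gene_cn = _weighted_mean_over(profile.segments, [tuple(sorted(x)) for x in gene.exons])
        status = AmpStatus.FULL_LENGTH_AMP if gene_cn > WGS_AMP_CN else AmpStatus.NONE
    return AmplificationCall(status, "WGS", cn17, cn18, profile.sample_id)


def call_amp_tcga(profile: CopyNumberProfile, gene: GeneModel) -> AmplificationCall:
    """log2(CN/2) segment rules with the GISTIC-style 0.3 threshold."""
    if profile.scale is not Scale.LOG2_RATIO:
        raise ValueError("TCGA rule set requires log2-ratio segment values")
    v17, v18 = _summaries(profile, gene)
    if (
        _break_in_last_intron(profile, gene)
        and v17 > TCGA_AMP_LOG2
        and v17 - v18 > TCGA_AMP_LOG2
    ):
        status = AmpStatus.PARTIAL_AMP_E1_E17
    else:
        gene_v = _weighted_mean_over(profile.segments, [tuple(sorted(x)) for x in gene.exons])
        status = AmpStatus.FULL_LENGTH_AMP if gene_v > TCGA_AMP_LOG2 else AmpStatus.NONE
    return AmplificationCall(status, "TCGA", v17, v18, profile.sample_id)


def call_amp_ccle(log2_ratio: float) -> bool:
    """Cell-line rule: log2(CN/2) >= 2 is an amplification."""
    return log2_ratio >= CCLE_AMP_LOG2


def call_amp_panel(
    exon_target_cn,
    median_ploidy: float,
    *,
    sample_id: str | None = None,
    e18_margin: float = 0.0,
) -> AmplificationCall:
    """Per-exon panel-target rules.

    Amplified-target threshold = 4 + median ploidy.  Partial E1-E17 calls
    require >= 80% of E1-E17 targets amplified while the E18 target stays
    below ``threshold - e18_margin`` (the differential-gain margin is
    configurable; default 0 = simply below the amplification threshold).
    """
    if exon_target_cn is None or len(exon_target_cn) < 2:
        raise ValueError("per-exon target copy numbers (>= 2 exons) are required")
    if median_ploidy <= 0:
        raise ValueError("median ploidy must be positive")
    cn = np.asarray(exon_target_cn, dtype=float)
    threshold = PANEL_CN_OVER_PLOIDY + median_ploidy
    cn17 = float(cn[:-1].mean())
    cn18 = float(cn[-1])
    frac_e1_e17 = float((cn[:-1] >= threshold).mean())
    frac_all = float((cn >= threshold).mean())
    if frac_e1_e17 >= PANEL_TARGET_FRACTION and cn18 < threshold - e18_margin:
        status = AmpStatus.PARTIAL_AMP_E1_E17
    elif frac_all >= PANEL_TARGET_FRACTION:
        status = AmpStatus.FULL_LENGTH_AMP
    else:
        status = AmpStatus.NONE
    return AmplificationCall(status, "PANEL", cn17, cn18, sample_id)


def read_seg(path, *, scale: Scale = Scale.ABSOLUTE_CN) -> dict[str, CopyNumberProfile]:
    """Read a SEG-like TSV (sample_id, chrom, start, end, value) into
    per-sample profiles; coordinates are 0-based half-open."""
    df = pd.read_csv(path, sep="\t")
    profiles = {}
    for sid, grp in df.groupby("sample_id", sort=True):
        segs = tuple(
            (int(r.start), int(r.end), float(r.value)) for r in grp.itertuples(index=False)
        )
        ploidy = float(grp["median_ploidy"].iloc[0]) if "median_ploidy" in grp else 2.0
        profiles[str(sid)] = CopyNumberProfile(str(sid), segs, None, ploidy, scale)
    return profiles


def read_exon_targets(path) -> dict[str, CopyNumberProfile]:
    """Read a per-exon-target TSV (sample_id, median_ploidy, E1..En columns)."""
    df = pd.read_csv(path, sep="\t")
    exon_cols = [c for c in df.columns if c.startswith("E") and c[1:].isdigit()]
    exon_cols.sort(key=lambda c: int(c[1:]))
    profiles = {}
    for r in df.itertuples(index=False):
        cn = tuple(float(getattr(r, c)) for c in exon_cols)
        profiles[str(r.sample_id)] = CopyNumberProfile(
            str(r.sample_id), (), cn, float(r.median_ploidy), Scale.ABSOLUTE_CN
        )
    return profiles
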