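"""Integration of DNA and RNA evidence into per-sample alteration
categories, cohort arithmetic and treatment-response ratios.

Every sample receives exactly one of four categories with precedence
E18_TRUNCATED > FL_AMP > HOTSPOT > WT:

E18_TRUNCATED  any last-intron/last-exon RE passing the allele-frequency
               threshold (in-frame fusion or non-canonical), an E1-E17
               partial amplification, an E18 splice-site mutation, a
               proximal E18-truncating mutation, or (optionally) RNA-level
               truncation evidence
FL_AMP         full-length gene amplification without truncating evidence
HOTSPOT        recurrent missense hotspot mutation only
WT             none of the above

Distal E18-truncating mutations are recorded but never trigger
E18_TRUNCATED (functionally they had limited transforming potential), and
an in-frame fusion co-occurring with a full-length amplification stays
E18_TRUNCATED with the dedicated FUSION_PLUS_AMP subgroup.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .cn_caller import AmplificationCall, AmpStatus
from .mutation_classifier import MutationCall, MutationCategory
from .sv_classifier import RearrangementCall, REType

__all__ = [
    "Category",
    "Subgroup",
    "SampleAlterationProfile",
    "CohortSummary",
    "TreatmentResponse",
    "assign_category",
    "cohort_summary",
    "delta_t_delta_c",
    "round_half_up",
]


class Category(str, enum.Enum):
    E18_TRUNCATED = "E18_TRUNCATED"
    FL_AMP = "FL_AMP"
    HOTSPOT = "HOTSPOT"
    WT = "WT"


class Subgroup(str, enum.Enum):
    IN_FRAME_FUSION = "IN_FRAME_FUSION"
    FRAME_UNKNOWN_RE = "FRAME_UNKNOWN_RE"
    INTERGENIC_RE = "INTERGENIC_RE"
    OUT_OF_STRAND_RE = "OUT_OF_STRAND_RE"
    INTERNAL_RE = "INTERNAL_RE"
    SPLICE_MUT = "SPLICE_MUT"
    PROXIMAL_TRUNC_MUT = "PROXIMAL_TRUNC_MUT"
    DISTAL_TRUNC_MUT = "DISTAL_TRUNC_MUT"
    PARTIAL_AMP = "PARTIAL_AMP"
    FUSION_PLUS_AMP = "FUSION_PLUS_AMP"
    RNA_TRUNCATED = "RNA_TRUNCATED"


_RE_SUBGROUP = {
    REType.IN_FRAME_FUSION: Subgroup.IN_FRAME_FUSION,
    REType.FRAME_UNKNOWN: Subgroup.FRAME_UNKNOWN_RE,
    REType.INTERGENIC_SPACE: Subgroup.INTERGENIC_RE,
    REType.OUT_OF_STRAND: Subgroup.OUT_OF_STRAND_RE,
    REType.INTERNAL: Subgroup.INTERNAL_RE,
}

#: fixed subgroup priority within E18_TRUNCATED (fusions first, as in the
#: cohort presentations; FUSION_PLUS_AMP overrides when amp co-occurs)
_RE_PRIORITY = [
    REType.IN_FRAME_FUSION,
    REType.FRAME_UNKNOWN,
    REType.INTERGENIC_SPACE,
    REType.OUT_OF_STRAND,
    REType.INTERNAL,
]


@dataclass(frozen=True)
class SampleAlterationProfile:
    sample_id: str
    category: Category
    subgroup: Subgroup | None
    tumour_type: str | None = None
    re_calls: tuple[RearrangementCall, ...] = ()
    amp_call: AmplificationCall | None = None
    mutations: tuple[MutationCall, ...] = ()
    annotations: tuple[str, ...] = ()


@dataclass(frozen=True)
class TreatmentResponse:
    delta_t: float
    delta_c: float
    ratio: float | None  # None marks an undefined ratio (control regression)


def round_half_up(value: float, decimals: int) -> float:
    """Decimal round-half-up at a fixed number of decimals (the convention
    used for all printed incidences and fractions)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def assign_category(
    sample_id: str,
    re_calls: list[RearrangementCall] = (),
    amp_call: AmplificationCall | None = None,
    mutations: list[MutationCall] = (),
    *,
    rna_truncated: bool | None = None,
    tumour_type: str | None = None,
) -> SampleAlterationProfile:
    """Combine evidence lines into one category + subgroup per sample."""
    if not re_calls and amp_call is None and not mutations and rna_truncated is None:
        raise ValueError(f"sample {sample_id}: no evidence lines provided")

    truncating_res = [c for c in re_calls if c.e18_truncating]
    amp_status = amp_call.status if amp_call is not None else AmpStatus.NONE
    mut_cats = {m.category for m in mutations}
    annotations = []
    if MutationCategory.DISTAL_TRUNCATING in mut_cats:
        annotations.append("distal_truncating_mutation")

    subgroup: Subgroup | None = None
    if truncating_res:
        by_type = {c.re_type: c for c in reversed(truncating_res)}
        top = next(t for t in _RE_PRIORITY if t in by_type)
        if top is REType.IN_FRAME_FUSION and amp_status is AmpStatus.FULL_LENGTH_AMP:
            subgroup = Subgroup.FUSION_PLUS_AMP
        else:
            subgroup = _RE_SUBGROUP[top]
    elif amp_status is AmpStatus.PARTIAL_AMP_E1_E17:
        subgroup = Subgroup.PARTIAL_AMP
    elif MutationCategory.E18_SPLICE in mut_cats:
        subgroup = Subgroup.SPLICE_MUT
    elif MutationCategory.PROXIMAL_TRUNCATING in mut_cats:
        subgroup = Subgroup.PROXIMAL_TRUNC_MUT
    elif rna_truncated:
        subgroup = Subgroup.RNA_TRUNCATED

    if subgroup is not None:
        category = Category.E18_TRUNCATED
    elif amp_status is AmpStatus.FULL_LENGTH_AMP:
        category = Category.FL_AMP
    elif MutationCategory.HOTSPOT in mut_cats:
        category = Category.HOTSPOT
    else:
        category = Category.WT
        if MutationCategory.DISTAL_TRUNCATING in mut_cats:
            subgroup = Subgroup.DISTAL_TRUNC_MUT

    if category is not Category.E18_TRUNCATED and subgroup not in (None, Subgroup.DISTAL_TRUNC_MUT):
        subgroup = None

    return SampleAlterationProfile(
        sample_id=sample_id,
        category=category,
        subgroup=subgroup if category in (Category.E18_TRUNCATED, Category.WT) else None,
        tumour_type=tumour_type,
        re_calls=tuple(re_calls),
        amp_call=amp_call,
        mutations=tuple(mutations),
        annotations=tuple(annotations),
    )


@dataclass(frozen=True)
class CohortSummary:
    """Counts, incidences (percent of assayed cohort, 2 decimals) and
    within-class fractions (percent of a class total, 1 decimal)."""

    counts: dict[str, int]
    total_assayed: int
    incidences: dict[str, float]
    fractions: dict[str, dict[str, float]]


def cohort_summary(
    counts: dict[str, int] | list[SampleAlterationProfile],
    total_assayed: int,
    *,
    class_totals: dict[str, tuple[str, ...]] | None = None,
) -> CohortSummary:
    """Cohort arithmetic from per-class counts (or profiles).

    incidence(class) = 100 * count / total_assayed, rounded half-up to two
    decimals; for every class listed in ``class_totals`` (mapping a class
    name to its member count keys) within-class fractions are
    100 * count / class_total, rounded half-up to one decimal.
    """
    if total_assayed <= 0:
        raise ValueError("total_assayed must be positive")
    if not isinstance(counts, dict):
        tallied: dict[str, int] = {}
        for p in counts:
            tallied[p.category.value] = tallied.get(p.category.value, 0) + 1
            if p.subgroup is not None:
                tallied[p.subgroup.value] = tallied.get(p.subgroup.value, 0) + 1
        counts = tallied
    n_profiles = sum(
        v for k, v in counts.items() if k in {c.value for c in Category}
    )
    if n_profiles > total_assayed:
        raise ValueError("category counts exceed the assayed total")

    incidences = {
        k: round_half_up(100.0 * v / total_assayed, 2) for k, v in counts.items()
    }
    fractions: dict[str, dict[str, float]] = {}
    for cls, members in (class_totals or {}).items():
        cls_total = counts[cls]
        if cls_total > 0:
            fractions[cls] = {
                m: round_half_up(100.0 * counts.get(m, 0) / cls_total, 1) for m in members
            }
    return CohortSummary(dict(counts), total_assayed, incidences, fractions)


def delta_t_delta_c(
    treated: np.ndarray | list[list[float]],
    control: np.ndarray | list[list[float]],
) -> TreatmentResponse:
    """Treatment-to-control tumour-volume response ratio.

    ``treated`` and ``control`` are per-animal volume series (animals x
    timepoints).  Delta = mean over animals of (last - first volume);
    ratio = delta_t / delta_c, undefined (None) when the control arm did
    not grow (delta_c <= 0).
    """
    t = np.atleast_2d(np.asarray(treated, dtype=float))
    c = np.atleast_2d(np.asarray(control, dtype=float))
    if t.shape[0] < 1 or c.shape[0] < 1 or t.shape[1] < 2 or c.shape[1] < 2:
        raise ValueError("each arm needs >= 1 animal and >= 2 timepoints")
    delta_t = float((t[:, -1] - t[:, 0]).mean())
    delta_c = float((c[:, -1] - c[:, 0]).mean())
    ratio = None if delta_c <= 0 else delta_t / delta_c
    return TreatmentResponse(delta_t, delta_c, ratio)
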