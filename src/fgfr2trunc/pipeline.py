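"""End-to-end driver: run every classifier over a cohort bundle and
integrate the evidence into per-sample alteration profiles.

This is the path the analysis scripts and acceptance checks exercise; each
step delegates to the corresponding module so the pipeline is exactly the
sum of its tested parts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import cn_caller, cohort_integrator, mutation_classifier, rna_evidence, sv_classifier
from .cn_caller import CopyNumberProfile, Scale
from .gene_model import GeneSet, annotate_breakend, SENSE, ANTISENSE
from .synthetic_cohort import CohortBundle

__all__ = ["classify_bundle_svs", "call_bundle_amps", "integrate_bundle"]

GENE_OF_INTEREST = "FGFR2"


def _orientation(strand: str, chrom: str, pos: int, models: GeneSet) -> str:
    genes = models.genes_at(chrom, pos)
    if genes:
        return SENSE if strand == genes[0].strand else ANTISENSE
    return SENSE


def classify_bundle_svs(bundle: CohortBundle, models: GeneSet) -> dict[str, list]:
    """Classify every BEDPE breakpoint pair; allele frequencies use the
    sample's mean gene copy number from its segment profile."""
    gene = models[GENE_OF_INTEREST]
    seg_by_sample = {
        sid: tuple((int(r.start), int(r.end), float(r.value)) for r in grp.itertuples(index=False))
        for sid, grp in bundle.seg.groupby("sample_id")
    }
    calls: dict[str, list] = {}
    for row in bundle.bedpe.itertuples(index=False):
        sid = str(row.sample_id)
        a = annotate_breakend(
            row.chrom1, int(row.start1),
            _orientation(row.strand1, row.chrom1, int(row.start1), models), models,
        )
        b = annotate_breakend(
            row.chrom2, int(row.start2),
            _orientation(row.strand2, row.chrom2, int(row.start2), models), models,
        )
        call = sv_classifier.classify_re(a, b, models, gene_of_interest=GENE_OF_INTEREST)
        segs = seg_by_sample.get(sid, ())
        exon_ivs = [tuple(sorted(x)) for x in gene.exons]
        gene_cn = cn_caller._weighted_mean_over(segs, exon_ivs) if segs else 2.0
        call = sv_classifier.compute_allele_frequency(
            call, gene_cn,
            junction_ploidy=float(row.junction_ploidy),
            gene_of_interest_model=gene,
        )
        calls.setdefault(sid, []).append(
            sv_classifier.RearrangementCall(**{**call.__dict__, "sample_id": sid})
        )
    return calls


def call_bundle_amps(bundle: CohortBundle, models: GeneSet, *, rule_set: str = "WGS") -> dict:
    """Amplification calls per sample from the bundle's SEG (WGS rules) or
    per-exon target table (PANEL rules)."""
    gene = models[GENE_OF_INTEREST]
    out = {}
    if rule_set == "WGS":
        for sid, grp in bundle.seg.groupby("sample_id"):
            profile = CopyNumberProfile(
                str(sid),
                tuple((int(r.start), int(r.end), float(r.value)) for r in grp.itertuples(index=False)),
                None, 2.0, Scale.ABSOLUTE_CN,
            )
            out[str(sid)] = cn_caller.call_amp_wgs(profile, gene)
    elif rule_set == "PANEL":
        n = gene.n_exons
        for r in bundle.exon_targets.itertuples(index=False):
            cn = [float(getattr(r, f"E{i + 1}")) for i in range(n)]
            out[str(r.sample_id)] = cn_caller.call_amp_panel(
                cn, float(r.median_ploidy), sample_id=str(r.sample_id)
            )
    else:
        raise ValueError("rule_set must be 'WGS' or 'PANEL'")
    return out


def integrate_bundle(
    bundle: CohortBundle,
    models: GeneSet,
    *,
    amp_rule_set: str = "WGS",
    use_rna: bool = False,
) -> pd.DataFrame:
    """Full integration: SV + CN + mutation (+ optional RNA) evidence to
    one category/subgroup per sample.  Returns a frame indexed by sample."""
    sv_calls = classify_bundle_svs(bundle, models)
    amp_calls = call_bundle_amps(bundle, models, rule_set=amp_rule_set)
    mut_calls: dict[str, list] = {}
    if len(bundle.maf):
        for r in bundle.maf.itertuples(index=False):
            change = str(r.protein_change) if str(r.protein_change) not in ("", "nan") else None
            mut_calls.setdefault(str(r.sample_id), []).append(
                mutation_classifier.classify_mutation(
                    str(r.gene), change,
                    consequence=str(r.consequence),
                    is_e18_splice_acceptor=bool(r.is_e18_splice_acceptor),
                    sample_id=str(r.sample_id),
                )
            )

    sample_ids = sorted(amp_calls)
    rows = []
    for sid in sample_ids:
        rna_flag = None
        if use_rna:
            usage = rna_evidence.acceptor_usage(bundle.junction_table(sid))
            rna_flag = rna_evidence.call_e18_truncated_rna(usage)
        profile = cohort_integrator.assign_category(
            sid,
            sv_calls.get(sid, []),
            amp_calls.get(sid),
            mut_calls.get(sid, []),
            rna_truncated=rna_flag,
        )
        rows.append(
            {
                "sample_id": sid,
                "category": profile.category.value,
                "subgroup": profile.subgroup.value if profile.subgroup else None,
                "n_re_calls": len(profile.re_calls),
                "amp_status": profile.amp_call.status.value if profile.amp_call else None,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")
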