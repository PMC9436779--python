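"""Synthetic cohorts with planted ground truth.

Generates every input the pipeline consumes — a toy gene annotation, SV
breakpoint pairs, copy-number segments and panel exon targets, small
variants, splice-junction counts, expression matrices and a co-driver
alteration matrix — from a single seed, together with the planted truth
(per-sample alteration kind and expected category, per-gene co-driver odds
ratios), so every stage is testable without restricted data.

The toy genome is one chromosome carrying an 18-exon FGFR2-like coding
gene (821 aa, last-intron breakpoint hotspot, alternative last exons C2/C3/
C4 annotated on non-coding transcripts), partner genes of differing protein
lengths, strands and splice phases, a non-coding gene and an intergenic
tract.  Simulation operates at the call/count level (no reads).

All randomness flows from one root ``numpy.random.SeedSequence`` split
into named child streams (sv, cn, mut, junction, expression, drivers), so
adding a generator does not perturb existing streams.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .gene_model import GeneModel, GeneSet, load_gene_models
from .rna_evidence import JunctionTable

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "CohortBundle",
    "toy_gtf",
    "toy_models",
    "make_toy_gene_fixtures",
    "simulate_cohort",
    "simulate_driver_cohort",
    "star_sj_lines",
    "DEFAULT_MIXTURE",
]

CHROM = "chrT"

# planted alteration kinds and their default cohort mixture; RE-kind mass
# loosely echoes the observed predominance of in-frame fusions among
# truncating alterations, with enough mass everywhere to exercise each rule
DEFAULT_MIXTURE: dict[str, float] = {
    "IN_FRAME_FUSION": 0.12,
    "FRAME_UNKNOWN": 0.05,
    "INTERGENIC_SPACE": 0.06,
    "OUT_OF_STRAND": 0.04,
    "INTERNAL": 0.03,
    "UNRESOLVED": 0.03,
    "PARTIAL_AMP": 0.05,
    "SPLICE_MUT": 0.03,
    "PROXIMAL_MUT": 0.04,
    "DISTAL_MUT": 0.03,
    "FULL_AMP": 0.12,
    "HOTSPOT": 0.10,
    "WT": 0.30,
}

RE_KINDS = ("IN_FRAME_FUSION", "FRAME_UNKNOWN", "INTERGENIC_SPACE", "OUT_OF_STRAND",
            "INTERNAL", "UNRESOLVED")

_KIND_CATEGORY = {
    "IN_FRAME_FUSION": "E18_TRUNCATED", "FRAME_UNKNOWN": "E18_TRUNCATED",
    "INTERGENIC_SPACE": "E18_TRUNCATED", "OUT_OF_STRAND": "E18_TRUNCATED",
    "INTERNAL": "E18_TRUNCATED", "UNRESOLVED": "WT",
    "PARTIAL_AMP": "E18_TRUNCATED", "SPLICE_MUT": "E18_TRUNCATED",
    "PROXIMAL_MUT": "E18_TRUNCATED", "DISTAL_MUT": "WT",
    "FULL_AMP": "FL_AMP", "HOTSPOT": "HOTSPOT", "WT": "WT",
}

_KIND_SUBGROUP = {
    "IN_FRAME_FUSION": "IN_FRAME_FUSION", "FRAME_UNKNOWN": "FRAME_UNKNOWN_RE",
    "INTERGENIC_SPACE": "INTERGENIC_RE", "OUT_OF_STRAND": "OUT_OF_STRAND_RE",
    "INTERNAL": "INTERNAL_RE", "PARTIAL_AMP": "PARTIAL_AMP",
    "SPLICE_MUT": "SPLICE_MUT", "PROXIMAL_MUT": "PROXIMAL_TRUNC_MUT",
    "DISTAL_MUT": "DISTAL_TRUNC_MUT",
}

_HOTSPOT_CHANGES = ["p.S252W", "p.C382R", "p.N549K", "p.K659E"]


# ---------------------------------------------------------------------------
# toy gene fixtures


def _gene_lines(gene_id, tx_id, chrom, strand, exons, cds, extra_tx=()):
    """GTF lines (1-based inclusive) for one gene, main transcript + extras."""
    out = []
    span_lo = min(s for s, _ in exons)
    span_hi = max(e for _, e in exons)
    for tid, tx_exons in extra_tx:
        span_lo = min(span_lo, min(s for s, _ in tx_exons))
        span_hi = max(span_hi, max(e for _, e in tx_exons))
    gene_attr = f'gene_id "{gene_id}";'
    out.append(f"{chrom}\ttoy\tgene\t{span_lo + 1}\t{span_hi}\t.\t{strand}\t.\t{gene_attr}")

    def tx_block(tid, tx_exons, tx_cds):
        attr = f'gene_id "{gene_id}"; transcript_id "{tid}";'
        lo = min(s for s, _ in tx_exons)
        hi = max(e for _, e in tx_exons)
        lines = [f"{chrom}\ttoy\ttranscript\t{lo + 1}\t{hi}\t.\t{strand}\t.\t{attr}"]
        for s, e in sorted(tx_exons):
            lines.append(f"{chrom}\ttoy\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t{attr}")
        for s, e in sorted(tx_cds):
            lines.append(f"{chrom}\ttoy\tCDS\t{s + 1}\t{e}\t.\t{strand}\t.\t{attr}")
        return lines

    out.extend(tx_block(tx_id, exons, cds))
    for tid, tx_exons in extra_tx:
        out.extend(tx_block(tid, tx_exons, []))
    return out


def _plus_gene(start, cds_lengths, intron_lengths):
    """Fully-coding plus-strand exon layout from CDS/intron lengths."""
    exons = []
    pos = start
    for i, L in enumerate(cds_lengths):
        exons.append((pos, pos + L))
        pos += L
        if i < len(cds_lengths) - 1:
            pos += intron_lengths[i]
    return exons


def toy_gtf() -> str:
    """The deterministic toy annotation (GTF text).

    FGFR2   + strand at 10 kb: 18 fully coding exons (CDS 2,466 nt, 821 aa),
            E17 ends at phase 1, 6 kb last intron hosting the alternative
            last exon C3; C2 overlaps the proximal canonical E18 and C4 lies
            downstream, both on non-coding transcripts.
    BICC1L  + strand, 974 aa (longer than FGFR2 => fusion backbone): intron
            1 phase-compatible with FGFR2-I17, intron 2 incompatible.
    SHORTP  + strand, 300 aa, intron 1 phase-compatible.
    MINUSP  - strand, 500 aa, intron 1 phase-compatible.
    LNC1    non-coding gene; positions beyond 700 kb are intergenic.
    """
    lines = ["##gtf: synthetic toy annotation (fgfr2trunc fixtures)"]

    # FGFR2: 16 x 140 + 116 + 110 = 2466 nt CDS; introns 2 kb, I17 = 6 kb
    fg_cds = [140] * 16 + [116, 110]
    fg_introns = [2000] * 16 + [6000]
    fg_exons = _plus_gene(10_000, fg_cds, fg_introns)
    e17_end = fg_exons[16][1]
    e18 = fg_exons[17]
    c3 = (e17_end + 2000, e17_end + 2200)           # inside I17
    c2 = (e18[0], e18[0] + 60)                       # proximal overlap with E18
    c4 = (e18[1] + 3000, e18[1] + 3250)              # downstream of E18
    lines += _gene_lines(
        "FGFR2", "FGFR2.t1", CHROM, "+", fg_exons, fg_exons,
        extra_tx=[
            ("FGFR2.c2", fg_exons[:17] + [c2]),
            ("FGFR2.c3", fg_exons[:17] + [c3]),
            ("FGFR2.c4", fg_exons[:17] + [c4]),
        ],
    )

    # BICC1L: 100 + 151 + 7 x 334 + 336 = 2925 nt (974 aa); introns 1.5 kb
    bi_cds = [100, 151] + [334] * 7 + [336]
    bi_exons = _plus_gene(200_000, bi_cds, [1500] * 9)
    lines += _gene_lines("BICC1L", "BICC1L.t1", CHROM, "+", bi_exons, bi_exons)

    # SHORTP: 121 + 120 + 120 + 542 = 903 nt (300 aa); introns 1 kb
    sp_cds = [121, 120, 120, 542]
    sp_exons = _plus_gene(400_000, sp_cds, [1000] * 3)
    lines += _gene_lines("SHORTP", "SHORTP.t1", CHROM, "+", sp_exons, sp_exons)

    # MINUSP (- strand): transcript-order CDS 100+200+400+400+403 = 1503 nt
    mi_cds_tx = [100, 200, 400, 400, 403]
    mi_exons_genomic = _plus_gene(500_000, list(reversed(mi_cds_tx)), [1000] * 4)
    lines += _gene_lines("MINUSP", "MINUSP.t1", CHROM, "-", mi_exons_genomic, mi_exons_genomic)

    # LNC1: non-coding two-exon gene
    lnc_exons = [(600_000, 600_400), (601_400, 601_900)]
    lines += _gene_lines("LNC1", "LNC1.t1", CHROM, "+", lnc_exons, [])

    return "\n".join(lines) + "\n"


def toy_models() -> GeneSet:
    """GeneSet of the toy annotation (canonical transcripts)."""
    return load_gene_models(io.StringIO(toy_gtf()))


def make_toy_gene_fixtures(out_dir, seed: int | None = None) -> Path:
    """Write the toy annotation to ``out_dir/genes.gtf``.

    The layout is a fixed deterministic fixture; ``seed`` is accepted for
    API symmetry and does not alter it.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "genes.gtf"
    path.write_text(toy_gtf())
    return path


def _intron(model: GeneModel, k: int) -> tuple[int, int]:
    a, b = model.exons[k - 1], model.exons[k]
    if model.strand == "+":
        return (a[1], b[0])
    return (b[1], a[0])


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    ``mixture`` gives the planted alteration-kind proportions (must sum to
    1); RE allele frequencies are drawn clear of the 0.15 threshold (pass:
    U(0.30, 0.95); fail, with probability ``af_fail_rate``: U(0.04, 0.10))
    so planted truth is unambiguous.  Junction counts are multinomial at
    ``junction_depth``; copy-number noise is Gaussian truncated at 0.
    """

    seed: int = 0
    n_samples: int = 1000
    mixture: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MIXTURE))
    af_fail_rate: float = 0.15
    baseline_cn: float = 2.0
    cn_noise_sd: float = 0.12
    amp_cn_range: tuple[float, float] = (6.5, 12.0)
    partial_e18_cn_range: tuple[float, float] = (1.5, 2.5)
    junction_depth: int = 200
    baseline_usage: dict[str, float] = field(
        default_factory=lambda: {"E18-C1": 0.97, "E18-C3": 0.02, "E18-C4": 0.01}
    )
    n_driver_genes: int = 20
    driver_baseline_rate: float = 0.10
    driver_log_or: dict[str, float] = field(default_factory=dict)  # category -> log OR
    n_normals: int = 5

    def validate(self) -> None:
        total = sum(self.mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture proportions must sum to 1, got {total}")
        if any(p < 0 for p in self.mixture.values()):
            raise ValueError("mixture proportions must be non-negative")
        unknown = set(self.mixture) - set(DEFAULT_MIXTURE)
        if unknown:
            raise ValueError(f"unknown mixture kinds: {sorted(unknown)}")
        if not 0 <= self.af_fail_rate <= 1:
            raise ValueError("af_fail_rate must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Planted truth: one row per sample (kind, allele frequency, expected
    category/subgroup, RNA usage) plus per-gene co-driver log odds ratios."""

    samples: pd.DataFrame
    driver_log_or: pd.DataFrame  # genes x categories
    driver_baseline_rate: float


@dataclass
class CohortBundle:
    """The simulated input files, as DataFrames (written as TSVs when an
    output directory is supplied)."""

    gtf: str
    bedpe: pd.DataFrame
    seg: pd.DataFrame
    exon_targets: pd.DataFrame
    maf: pd.DataFrame
    junctions: pd.DataFrame          # long format: sample_id, donor, acceptor, unique_reads
    exon_expression: pd.DataFrame    # samples (+normals) x E1..E18, with is_normal column
    fgfr_expression: pd.DataFrame    # samples x FGFR1..FGFR4
    driver_matrix: pd.DataFrame      # samples x driver genes (0/1)

    def junction_table(self, sample_id: str) -> JunctionTable:
        sub = self.junctions[self.junctions["sample_id"] == sample_id]
        entries = tuple(
            (r.donor, r.acceptor, int(r.unique_reads)) for r in sub.itertuples(index=False)
        )
        return JunctionTable(sample_id, entries)


def _uniform_pos(rng, interval: tuple[int, int], margin: int = 10) -> int:
    lo, hi = interval
    return int(rng.integers(lo + margin, hi - margin))


def simulate_cohort(config: SimulationConfig, out_dir=None) -> tuple[CohortBundle, GroundTruth]:
    """Generate one cohort; identical config (incl. seed) reproduces the
    bundle byte-identically."""
    config.validate()
    root = np.random.SeedSequence(config.seed)
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("assign", "sv", "cn", "mut", "junction", "expression", "drivers"),
            root.spawn(7),
        )
    }

    models = toy_models()
    fgfr2 = models["FGFR2"]
    bicc1l = models["BICC1L"]
    minusp = models["MINUSP"]
    i17 = _intron(fgfr2, 17)
    i3 = _intron(fgfr2, 3)
    bicc_i1 = _intron(bicc1l, 1)   # phase-compatible with FGFR2-I17
    bicc_i2 = _intron(bicc1l, 2)   # phase-incompatible
    minus_i1 = _intron(minusp, 1)  # phase-compatible, minus strand
    igr = (700_000, 800_000)
    c3_exon = (i17[0] + 2000, i17[0] + 2200)

    kinds = list(config.mixture)
    probs = np.array([config.mixture[k] for k in kinds])
    rng = streams["assign"]
    sample_kinds = rng.choice(kinds, size=config.n_samples, p=probs)
    sample_ids = [f"S{i:04d}" for i in range(config.n_samples)]

    sv_rng = streams["sv"]
    cn_rng = streams["cn"]
    mut_rng = streams["mut"]
    jx_rng = streams["junction"]
    ex_rng = streams["expression"]
    dr_rng = streams["drivers"]

    truth_rows = []
    bedpe_rows = []
    seg_rows = []
    target_rows = []
    maf_rows = []
    junction_rows = []
    expr_rows = []

    gene_lo, gene_hi = fgfr2.span
    seg_span = (gene_lo - 5000, gene_hi + 5000)
    n_exons = fgfr2.n_exons

    for sid, kind in zip(sample_ids, sample_kinds):
        af = np.nan
        af_pass = False
        partner_acceptor = None

        # --- structural variants (BEDPE rows; FGFR2 side first) ---
        if kind in RE_KINDS:
            af_pass = kind != "UNRESOLVED" and sv_rng.random() >= config.af_fail_rate
            af = (
                sv_rng.uniform(0.30, 0.95) if af_pass or kind == "UNRESOLVED"
                else sv_rng.uniform(0.04, 0.10)
            )
            pos_a = _uniform_pos(sv_rng, i17)
            # keep the FGFR2 breakend clear of the C3 alternative exon
            while c3_exon[0] - 10 <= pos_a < c3_exon[1] + 10:
                pos_a = _uniform_pos(sv_rng, i17)
            strand_a = "-" if kind == "UNRESOLVED" else "+"
            if kind == "IN_FRAME_FUSION":
                if sv_rng.random() < 0.5:
                    pos_b, strand_b = _uniform_pos(sv_rng, bicc_i1), "+"
                    partner_acceptor = "partner:BICC1L"
                else:  # sense on a minus-strand gene = '-' read strand
                    pos_b, strand_b = _uniform_pos(sv_rng, minus_i1), "-"
                    partner_acceptor = "partner:MINUSP"
            elif kind == "FRAME_UNKNOWN":
                pos_b, strand_b = _uniform_pos(sv_rng, bicc_i2), "+"
                partner_acceptor = "partner:BICC1L"
            elif kind == "OUT_OF_STRAND":
                pos_b, strand_b = _uniform_pos(sv_rng, bicc_i1), "-"
                partner_acceptor = "partner:BICC1L"
            elif kind == "INTERGENIC_SPACE":
                pos_b, strand_b = _uniform_pos(sv_rng, igr), "+"
                partner_acceptor = "IGR"
            elif kind == "INTERNAL":
                pos_b, strand_b = _uniform_pos(sv_rng, i3), "+"
                partner_acceptor = None
            else:  # UNRESOLVED: partner irrelevant, classifier stops at rule 6
                pos_b, strand_b = _uniform_pos(sv_rng, bicc_i1), "+"
                partner_acceptor = "partner:BICC1L"
            gene_cn_for_af = config.baseline_cn
            bedpe_rows.append(
                {
                    "chrom1": CHROM, "start1": pos_a, "end1": pos_a + 1,
                    "chrom2": CHROM, "start2": pos_b, "end2": pos_b + 1,
                    "name": f"{sid}_re", "score": ".",
                    "strand1": strand_a, "strand2": strand_b,
                    "sample_id": sid, "junction_ploidy": af * gene_cn_for_af,
                }
            )

        # --- copy number (SEG + panel exon targets) ---
        noise = lambda: max(cn_rng.normal(0.0, config.cn_noise_sd), -1.0)
        base = config.baseline_cn
        if kind == "FULL_AMP":
            amp = cn_rng.uniform(*config.amp_cn_range)
            seg_rows.append({"sample_id": sid, "chrom": CHROM, "start": seg_span[0],
                             "end": seg_span[1], "value": amp + noise()})
            targets = [max(amp + noise(), 0) for _ in range(n_exons)]
        elif kind == "PARTIAL_AMP":
            amp = cn_rng.uniform(*config.amp_cn_range)
            e18_cn = cn_rng.uniform(*config.partial_e18_cn_range)
            split = _uniform_pos(cn_rng, i17)
            seg_rows.append({"sample_id": sid, "chrom": CHROM, "start": seg_span[0],
                             "end": split, "value": amp + noise()})
            seg_rows.append({"sample_id": sid, "chrom": CHROM, "start": split,
                             "end": seg_span[1], "value": e18_cn + noise()})
            targets = [max(amp + noise(), 0) for _ in range(n_exons - 1)]
            targets.append(max(e18_cn + noise(), 0))
        else:
            seg_rows.append({"sample_id": sid, "chrom": CHROM, "start": seg_span[0],
                             "end": seg_span[1], "value": max(base + noise(), 0)})
            targets = [max(base + noise(), 0) for _ in range(n_exons)]
        target_rows.append({"sample_id": sid, "median_ploidy": config.baseline_cn,
                            **{f"E{i + 1}": t for i, t in enumerate(targets)}})

        # --- small variants (MAF-like) ---
        if kind == "HOTSPOT":
            maf_rows.append({"sample_id": sid, "gene": "FGFR2",
                             "protein_change": _HOTSPOT_CHANGES[mut_rng.integers(4)],
                             "consequence": "missense", "is_e18_splice_acceptor": False})
        elif kind == "SPLICE_MUT":
            maf_rows.append({"sample_id": sid, "gene": "FGFR2", "protein_change": "",
                             "consequence": "splice_site", "is_e18_splice_acceptor": True})
        elif kind == "PROXIMAL_MUT":
            pos = int(mut_rng.integers(768, 784))
            maf_rows.append({"sample_id": sid, "gene": "FGFR2",
                             "protein_change": f"p.Q{pos}*",
                             "consequence": "nonsense", "is_e18_splice_acceptor": False})
        elif kind == "DISTAL_MUT":
            pos = int(mut_rng.integers(784, 822))
            maf_rows.append({"sample_id": sid, "gene": "FGFR2",
                             "protein_change": f"p.S{pos}fs",
                             "consequence": "frameshift", "is_e18_splice_acceptor": False})

        # --- splice junctions from the E17 donor (multinomial at depth) ---
        usage = dict(config.baseline_usage)
        if partner_acceptor is not None and kind != "UNRESOLVED":
            scale = 1.0 - af
            usage = {acc: f * scale for acc, f in usage.items()}
            usage[partner_acceptor] = af
        elif kind == "INTERNAL" and af_pass:
            # internal REs remove E18 from a fraction of transcripts: reads
            # re-route to the alternative last exon C3
            usage = {"E18-C1": (1 - af) * 0.97, "E18-C3": af + (1 - af) * 0.02,
                     "E18-C4": (1 - af) * 0.01}
        accs = sorted(usage)
        counts = jx_rng.multinomial(config.junction_depth, [usage[a] / sum(usage.values()) for a in accs])
        for acc, cnt in zip(accs, counts):
            junction_rows.append({"sample_id": sid, "donor": "E17", "acceptor": acc,
                                  "unique_reads": int(cnt)})
        planted_c3 = usage.get("E18-C3", 0.0) / sum(usage.values())

        # --- exon expression (E18 loss for truncating kinds) ---
        level = float(ex_rng.lognormal(np.log(10.0), 0.15))
        row = {f"E{i + 1}": level * float(ex_rng.lognormal(0, 0.05)) for i in range(n_exons)}
        if _KIND_CATEGORY[kind] == "E18_TRUNCATED":
            row[f"E{n_exons}"] = level * 0.08
        expr_rows.append({"sample_id": sid, "is_normal": False, **row})

        truth_rows.append(
            {
                "sample_id": sid, "kind": kind, "allele_frequency": af,
                "af_pass": af_pass,
                "category": "WT" if kind in RE_KINDS and not af_pass and kind != "UNRESOLVED"
                else _KIND_CATEGORY[kind],
                "subgroup": _KIND_SUBGROUP.get(kind) if
                (kind not in RE_KINDS or af_pass) else None,
                "c3_usage": planted_c3,
            }
        )

    # normals for the expression reference
    for j in range(config.n_normals):
        level = float(ex_rng.lognormal(np.log(10.0), 0.1))
        row = {f"E{i + 1}": level * float(ex_rng.lognormal(0, 0.05)) for i in range(n_exons)}
        expr_rows.append({"sample_id": f"N{j:02d}", "is_normal": True, **row})

    truth = pd.DataFrame(truth_rows).set_index("sample_id")

    # FGFR1-4 expression: lognormal baseline, receptor-specific scale
    fgfr = pd.DataFrame(
        ex_rng.lognormal(np.log([8.0, 10.0, 6.0, 4.0]), 0.4, size=(config.n_samples, 4)),
        index=sample_ids, columns=["FGFR1", "FGFR2", "FGFR3", "FGFR4"],
    )

    # driver matrix with per-category planted log odds ratios
    genes = [f"DRV{g:02d}" for g in range(config.n_driver_genes)]
    base_logit = np.log(config.driver_baseline_rate / (1 - config.driver_baseline_rate))
    log_or = pd.DataFrame(0.0, index=genes,
                          columns=["E18_TRUNCATED", "FL_AMP", "HOTSPOT", "WT"])
    for cat, lo in config.driver_log_or.items():
        log_or[cat] = lo
    cat_per_sample = truth["category"].reindex(sample_ids).to_numpy()
    logits = base_logit + log_or.loc[:, cat_per_sample].to_numpy().T  # samples x genes
    pmat = 1.0 / (1.0 + np.exp(-logits))
    driver = pd.DataFrame(
        (dr_rng.random(pmat.shape) < pmat).astype(int), index=sample_ids, columns=genes
    )

    bundle = CohortBundle(
        gtf=toy_gtf(),
        bedpe=pd.DataFrame(bedpe_rows),
        seg=pd.DataFrame(seg_rows),
        exon_targets=pd.DataFrame(target_rows),
        maf=pd.DataFrame(maf_rows),
        junctions=pd.DataFrame(junction_rows),
        exon_expression=pd.DataFrame(expr_rows),
        fgfr_expression=fgfr,
        driver_matrix=driver,
    )
    ground_truth = GroundTruth(truth, log_or, config.driver_baseline_rate)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "genes.gtf").write_text(bundle.gtf)
        bundle.bedpe.to_csv(out / "sv.bedpe.tsv", sep="\t", index=False)
        bundle.seg.to_csv(out / "cn.seg.tsv", sep="\t", index=False)
        bundle.exon_targets.to_csv(out / "cn.exon_targets.tsv", sep="\t", index=False)
        bundle.maf.to_csv(out / "mutations.maf.tsv", sep="\t", index=False)
        bundle.junctions.to_csv(out / "junctions.tsv", sep="\t", index=False)
        bundle.exon_expression.to_csv(out / "exon_expression.tsv", sep="\t", index=False)
        bundle.fgfr_expression.to_csv(out / "fgfr_expression.tsv", sep="\t")
        bundle.driver_matrix.to_csv(out / "driver_matrix.tsv", sep="\t")
        truth.to_csv(out / "ground_truth.tsv", sep="\t")

    return bundle, ground_truth


def simulate_driver_cohort(
    seed: int | np.random.SeedSequence,
    n_samples: int = 2000,
    *,
    n_genes: int = 20,
    baseline_rate: float = 0.10,
    log_or: dict[str, float] | None = None,
    category_proportions: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Driver-matrix-only cohort (vectorised) for statistical calibration.

    Categories are drawn from ``category_proportions`` (default 30/15/10/45
    E18_TRUNCATED/FL_AMP/HOTSPOT/WT); each gene is altered independently
    with probability sigmoid(logit(baseline) + log OR of the sample's
    category).  ``log_or`` maps a category to a scalar (all genes) or a
    length-``n_genes`` vector of planted log odds ratios.  Returns
    (binary matrix samples x genes, category labels).
    """
    rng = np.random.default_rng(seed)
    props = category_proportions or {
        "E18_TRUNCATED": 0.30, "FL_AMP": 0.15, "HOTSPOT": 0.10, "WT": 0.45,
    }
    cats = list(props)
    labels = rng.choice(cats, size=n_samples, p=[props[c] for c in cats])
    base_logit = np.log(baseline_rate / (1 - baseline_rate))
    shift = np.zeros((n_samples, n_genes))
    for cat, lo in (log_or or {}).items():
        shift[labels == cat] = np.broadcast_to(np.asarray(lo, dtype=float), (n_genes,))
    p = 1.0 / (1.0 + np.exp(-(base_logit + shift)))
    mat = (rng.random((n_samples, n_genes)) < p).astype(int)
    idx = [f"S{i:05d}" for i in range(n_samples)]
    genes = [f"DRV{g:02d}" for g in range(n_genes)]
    return (
        pd.DataFrame(mat, index=idx, columns=genes),
        pd.Series(labels, index=idx, name="category"),
    )


def star_sj_lines(table: JunctionTable, donor_coords: dict[str, int],
                  acceptor_coords: dict[str, int]) -> str:
    """Render a JunctionTable in the STAR SJ.out.tab dialect (intron
    coordinates 1-based inclusive, unique-read counts in column 7)."""
    lines = []
    for donor, acceptor, n in table.entries:
        start = donor_coords[donor] + 1     # intron start, 1-based
        end = acceptor_coords[acceptor]     # intron end, 1-based
        lines.append(f"{CHROM}\t{start}\t{end}\t1\t1\t1\t{n}\t0\t50")
    return "\n".join(lines) + "\n"
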