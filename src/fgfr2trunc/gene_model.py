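"""Gene structures and reading-frame arithmetic.

Internal coordinates are 0-based half-open; GTF I/O converts to/from the
1-based inclusive dialect at the boundary.  Exon and intron indices are
1-based in transcript order, so for an 18-exon gene "I17" is the intron
between exons 17 and 18 regardless of strand.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gffutils
from intervaltree import IntervalTree

__all__ = [
    "GeneModel",
    "GenomicBreakend",
    "ExonPhase",
    "GeneSet",
    "GeneNotFoundError",
    "NonCodingModelError",
    "load_gene_models",
    "write_gtf",
    "compute_exon_phases",
    "annotate_breakend",
]

SENSE = "sense"
ANTISENSE = "antisense"


class GeneNotFoundError(KeyError):
    """A requested gene id is absent from the annotation."""


class NonCodingModelError(ValueError):
    """A coding model was required but the gene has no CDS."""


@dataclass(frozen=True)
class GeneModel:
    """Canonical-transcript model of one gene.

    ``exons`` and ``cds_intervals`` are (start, end) genomic intervals in
    transcript order: ascending genomic coordinates on '+', descending on '-'.
    ``protein_length`` counts amino acids excluding the stop codon.
    """

    gene_id: str
    chromosome: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_intervals: tuple[tuple[int, int], ...]
    coding: bool
    protein_length: int | None = None
    transcript_id: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> tuple[int, int]:
        starts = [s for s, _ in self.exons]
        ends = [e for _, e in self.exons]
        return min(starts), max(ends)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_intervals)

    def exon_index_at(self, position: int) -> int | None:
        """1-based transcript-order exon index containing ``position``."""
        for i, (s, e) in enumerate(self.exons, start=1):
            if s <= position < e:
                return i
        return None

    def intron_index_at(self, position: int) -> int | None:
        """1-based index of the intron containing ``position`` (I_k lies
        between exons k and k+1 in transcript order)."""
        lo, hi = self.span
        if not (lo <= position < hi):
            return None
        if self.exon_index_at(position) is not None:
            return None
        for k in range(self.n_exons - 1):
            a, b = self.exons[k], self.exons[k + 1]
            if self.strand == "+":
                gap = (a[1], b[0])
            else:
                gap = (b[1], a[0])
            if gap[0] <= position < gap[1]:
                return k + 1
        return None

    def cds_in_exon(self, exon_index: int) -> tuple[int, int] | None:
        """CDS interval inside the 1-based ``exon_index``, or None."""
        s, e = self.exons[exon_index - 1]
        for cs, ce in self.cds_intervals:
            if cs >= s and ce <= e:
                return (cs, ce)
        return None


@dataclass(frozen=True)
class ExonPhase:
    """Codon phase at which an exon's coding sequence starts and ends."""

    exon_index: int
    start_phase: int
    end_phase: int


@dataclass(frozen=True)
class GenomicBreakend:
    """One side of a rearrangement junction.

    ``context`` is ``("intron", gene_id, k)``, ``("exon", gene_id, k)`` or
    ``("intergenic",)``.  ``read_orientation`` is the orientation of the
    supporting read sequence relative to the annotated gene's coding strand.
    """

    chromosome: str
    position: int
    read_orientation: str
    context: tuple

    @property
    def is_intergenic(self) -> bool:
        return self.context[0] == "intergenic"

    @property
    def gene_id(self) -> str | None:
        return None if self.is_intergenic else self.context[1]

    @property
    def feature(self) -> str:
        return self.context[0]

    @property
    def index(self) -> int | None:
        return None if self.is_intergenic else self.context[2]


class GeneSet:
    """Collection of GeneModels with interval-indexed breakend lookup."""

    def __init__(self, models: Iterable[GeneModel]):
        self._models: dict[str, GeneModel] = {m.gene_id: m for m in models}
        self._trees: dict[str, IntervalTree] = {}
        for m in self._models.values():
            lo, hi = m.span
            self._trees.setdefault(m.chromosome, IntervalTree()).addi(lo, hi, m.gene_id)

    def __getitem__(self, gene_id: str) -> GeneModel:
        try:
            return self._models[gene_id]
        except KeyError:
            raise GeneNotFoundError(gene_id) from None

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._models

    def __iter__(self):
        return iter(self._models.values())

    def __len__(self) -> int:
        return len(self._models)

    def genes_at(self, chromosome: str, position: int) -> list[GeneModel]:
        tree = self._trees.get(chromosome)
        if tree is None:
            return []
        return sorted(
            (self._models[iv.data] for iv in tree.at(position)),
            key=lambda m: m.gene_id,
        )


def _transcript_order(intervals: list[tuple[int, int]], strand: str) -> tuple[tuple[int, int], ...]:
    return tuple(sorted(intervals, reverse=(strand == "-")))


def load_gene_models(
    annotation_source: str | io.TextIOBase,
    gene_ids: Iterable[str] | None = None,
    *,
    require_coding: bool = False,
) -> GeneSet:
    """Load canonical-transcript GeneModels from GTF/GFF3.

    The canonical transcript is the one with the longest total CDS, ties
    broken by lexicographic transcript id; transcripts without CDS rank by
    total exon length below any coding transcript.

    Parameters
    ----------
    annotation_source
        Path to a GTF/GFF3 file, or an open text stream of GTF data.
    gene_ids
        Genes to load; ``None`` loads every gene in the annotation.
    require_coding
        If true, a selected gene without any coding transcript raises
        :class:`NonCodingModelError`.
    """
    if hasattr(annotation_source, "read"):
        data = annotation_source.read()
        db = gffutils.create_db(
            data, ":memory:", from_string=True, merge_strategy="create_unique",
            keep_order=True, disable_infer_genes=True, disable_infer_transcripts=True,
        )
    else:
        db = gffutils.create_db(
            str(annotation_source), ":memory:", merge_strategy="create_unique",
            keep_order=True, disable_infer_genes=True, disable_infer_transcripts=True,
        )

    wanted = None if gene_ids is None else set(gene_ids)
    if wanted is not None and not wanted:
        return GeneSet([])

    by_gene: dict[str, list] = {}
    for tx in db.features_of_type(("transcript", "mRNA")):
        gid = tx.attributes.get("gene_id", [tx.id])[0]
        if wanted is not None and gid not in wanted:
            continue
        by_gene.setdefault(gid, []).append(tx)

    if wanted is not None:
        missing = wanted - set(by_gene)
        if missing:
            raise GeneNotFoundError(f"gene not found: {sorted(missing)}")

    models = []
    for gid, transcripts in by_gene.items():
        def sort_key(tx):
            cds_len = sum(f.end - f.start + 1 for f in db.children(tx, featuretype="CDS"))
            exon_len = sum(f.end - f.start + 1 for f in db.children(tx, featuretype="exon"))
            # longest CDS wins; among non-coding, longest exonic span wins;
            # ties broken by transcript id (ascending => take first)
            return (-cds_len, -exon_len, tx.id)

        tx = sorted(transcripts, key=sort_key)[0]
        exons = [(f.start - 1, f.end) for f in db.children(tx, featuretype="exon")]
        cds = [(f.start - 1, f.end) for f in db.children(tx, featuretype="CDS")]
        if not exons:
            continue
        strand = tx.strand
        coding = bool(cds)
        if require_coding and not coding:
            raise NonCodingModelError(f"non-coding model for gene {gid}")
        cds_total = sum(e - s for s, e in cds)
        protein_length = cds_total // 3 - 1 if coding else None
        models.append(
            GeneModel(
                gene_id=gid,
                chromosome=tx.seqid,
                strand=strand,
                exons=_transcript_order(exons, strand),
                cds_intervals=_transcript_order(cds, strand),
                coding=coding,
                protein_length=protein_length,
                transcript_id=tx.id,
            )
        )
    return GeneSet(models)


def write_gtf(models: Iterable[GeneModel], path: str) -> None:
    """Write GeneModels back to GTF (1-based inclusive coordinates)."""
    lines = []
    for m in models:
        lo, hi = m.span
        tx_id = m.transcript_id or f"{m.gene_id}.t1"
        attrs = f'gene_id "{m.gene_id}"; transcript_id "{tx_id}";'
        gene_attrs = f'gene_id "{m.gene_id}";'
        lines.append((m.chromosome, lo, "gene", lo + 1, hi, m.strand, gene_attrs))
        lines.append((m.chromosome, lo, "transcript", lo + 1, hi, m.strand, attrs))
        for s, e in sorted(m.exons):
            lines.append((m.chromosome, s, "exon", s + 1, e, m.strand, attrs))
        for s, e in sorted(m.cds_intervals):
            lines.append((m.chromosome, s, "CDS", s + 1, e, m.strand, attrs))
    with open(path, "w") as fh:
        for chrom, _, feat, start, end, strand, attrs in lines:
            fh.write(
                f"{chrom}\tfgfr2trunc\t{feat}\t{start}\t{end}\t.\t{strand}\t.\t{attrs}\n"
            )


def compute_exon_phases(model: GeneModel) -> list[ExonPhase]:
    """Codon phases of every coding exon, by cumulative CDS length mod 3.

    The first coding exon starts at phase 0; phase chains across the
    transcript: start_phase(k+1) == end_phase(k).
    """
    if not model.coding:
        raise NonCodingModelError(f"gene {model.gene_id} is non-coding")
    phases = []
    cum = 0
    for idx in range(1, model.n_exons + 1):
        cds = model.cds_in_exon(idx)
        if cds is None:
            continue
        length = cds[1] - cds[0]
        start_phase = cum % 3
        cum += length
        phases.append(ExonPhase(idx, start_phase, cum % 3))
    return phases


def annotate_breakend(
    chromosome: str,
    position: int,
    read_orientation: str,
    models: GeneSet,
) -> GenomicBreakend:
    """Assign gene context to a breakend by interval lookup.

    A position outside every gene span is intergenic; inside a gene but
    outside its exons it is intronic with the correct 1-based index.  When
    gene spans overlap the lexicographically first gene id wins.
    """
    for m in models.genes_at(chromosome, position):
        exon = m.exon_index_at(position)
        if exon is not None:
            return GenomicBreakend(chromosome, position, read_orientation, ("exon", m.gene_id, exon))
        intron = m.intron_index_at(position)
        if intron is not None:
            return GenomicBreakend(chromosome, position, read_orientation, ("intron", m.gene_id, intron))
    return GenomicBreakend(chromosome, position, read_orientation, ("intergenic",))
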