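"""Write the toy gene annotation and report its structure.

Emits results/fixtures/genes.gtf: an 18-exon FGFR2-like coding gene with a
last-intron breakpoint hotspot and alternative last exons C2/C3/C4, plus
fusion-partner genes of differing protein lengths, strands and splice
phases, a non-coding gene and an intergenic tract.
"""

from pathlib import Path

from fgfr2trunc.gene_model import compute_exon_phases
from fgfr2trunc.synthetic_cohort import make_toy_gene_fixtures, toy_models

OUT = Path(__file__).resolve().parents[1] / "results" / "fixtures"


def main() -> None:
    path = make_toy_gene_fixtures(OUT)
    models = toy_models()
    print(f"wrote {path}")
    for m in models:
        tail = f"{m.protein_length} aa" if m.coding else "non-coding"
        print(f"  {m.gene_id:8s} {m.strand} {m.n_exons:2d} exons  {tail}")
    fgfr2 = models["FGFR2"]
    phases = {p.exon_index: p for p in compute_exon_phases(fgfr2)}
    print(f"FGFR2 E17 ends at phase {phases[17].end_phase} "
          f"(the frame a compatible fusion partner must resume)")


if __name__ == "__main__":
    main()
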