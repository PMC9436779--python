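import numpy as np
import pytest

from fgfr2trunc.synthetic_cohort import SimulationConfig, simulate_cohort, toy_models


@pytest.fixture(scope="session")
def models():
    return toy_models()


@pytest.fixture(scope="session")
def fgfr2(models):
    return models["FGFR2"]


@pytest.fixture(scope="session")
def small_cohort():
    """A 250-sample cohort shared across tests (seed fixed)."""
    return simulate_cohort(SimulationConfig(seed=7, n_samples=250))


def make_random_gene(rng, gene_id, chromosome="chrR", start=None, strand="+",
                     max_exons=8, max_cds=300):
    """Random fully coding toy gene for frame-oracle tests."""
    from fgfr2trunc.gene_model import GeneModel

    n_exons = int(rng.integers(2, max_exons + 1))
    cds_lengths = rng.integers(1, max_cds + 1, size=n_exons)
    # pad the final exon so the total CDS is a whole number of codons
    cds_lengths[-1] += (-int(cds_lengths.sum())) % 3
    introns = rng.integers(50, 500, size=n_exons - 1)
    start = int(rng.integers(1000, 100_000)) if start is None else start
    genomic = []
    pos = start
    for i, L in enumerate(cds_lengths):
        genomic.append((pos, pos + int(L)))
        pos += int(L)
        if i < n_exons - 1:
            pos += int(introns[i])
    order = tuple(sorted(genomic, reverse=(strand == "-")))
    total = int(cds_lengths.sum())
    return GeneModel(
        gene_id=gene_id, chromosome=chromosome, strand=strand,
        exons=order, cds_intervals=order, coding=True,
        protein_length=total // 3 - 1,
    )
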