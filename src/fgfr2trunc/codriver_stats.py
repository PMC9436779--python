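"""Co-driver enrichment statistics across FGFR2 alteration categories.

Two complementary tests over a samples x driver-genes binary alteration
matrix labelled with the four-category FGFR2 status:

* one-tailed pooled proportion Z-tests for enrichment of a co-driver in a
  focal category (by default versus the union of the other two
  FGFR2-altered categories);
* two-tailed Fisher's exact tests of each altered category versus FGFR2-WT
  samples, reporting the odds ratio (Haldane-Anscombe +0.5 on all cells
  when any cell is zero) with a Woolf-style 95% CI on log OR.

P values are Benjamini-Hochberg adjusted within each analysis family x
category gene list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort_integrator import Category

__all__ = [
    "EnrichmentResult",
    "proportion_z_enrichment",
    "fisher_exact_two_sided",
    "two_sided_pvalues_for_margins",
    "fisher_cooccurrence",
    "bh_adjust",
    "run_enrichment",
]

ALTERED_CATEGORIES = (Category.E18_TRUNCATED, Category.FL_AMP, Category.HOTSPOT)

# relative tolerance when summing hypergeometric point probabilities
# <= the observed one (guards against floating-point ties)
_REL_TOL = 1.0 + 1e-7


@dataclass(frozen=True)
class EnrichmentResult:
    gene: str
    category: str
    a: int  # focal category, gene altered
    b: int  # focal category, gene not altered
    c: int  # comparison group, gene altered
    d: int  # comparison group, gene not altered
    proportion_z: float | None = None
    p_z: float | None = None
    odds_ratio: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    p_fisher: float | None = None
    q: float | None = None


def proportion_z_enrichment(
    x1: int, n1: int, x2: int, n2: int
) -> tuple[float, float]:
    """One-tailed (upper) pooled two-proportion Z-test.

    Z = (p1 - p2) / sqrt(p_hat (1 - p_hat) (1/n1 + 1/n2)) with the pooled
    proportion p_hat = (x1 + x2) / (n1 + n2); p is the upper normal tail.
    A degenerate pooled proportion (0 or 1) carries no evidence: returns
    (0, 1) with a warning.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("both groups must be non-empty")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled <= 0 or pooled >= 1:
        warnings.warn("degenerate pooled proportion: Z-test uninformative")
        return 0.0, 1.0
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (x1 / n1 - x2 / n2) / se
    return float(z), float(stats.norm.sf(z))


def two_sided_pvalues_for_margins(n: int, row1: int, col1: int) -> np.ndarray:
    """Two-tailed Fisher p for every table with margins (row1, n-row1) x
    (col1, n-col1), indexed by a = max(0, row1+col1-n) .. min(row1, col1).

    Each p is the point-probability sum: hypergeometric probabilities of
    all tables no more probable than the observed one.
    """
    if n == 0 or row1 == 0 or row1 == n or col1 == 0 or col1 == n:
        raise ValueError("Fisher test undefined for an empty margin")
    kmin = max(0, row1 + col1 - n)
    kmax = min(row1, col1)
    support = np.arange(kmin, kmax + 1)
    pmf = stats.hypergeom.pmf(support, n, col1, row1)
    mask = pmf[None, :] <= pmf[:, None] * _REL_TOL
    return np.minimum((mask * pmf[None, :]).sum(axis=1), 1.0)


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher exact p by point-probability summation: the sum of
    hypergeometric probabilities of all tables with the same margins that
    are no more probable than the observed table."""
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    kmin = max(0, row1 + col1 - n)
    return float(two_sided_pvalues_for_margins(n, row1, col1)[a - kmin])


def fisher_cooccurrence(
    matrix: pd.DataFrame,
    categories: pd.Series,
    gene: str,
    category: Category | str,
    *,
    reference: Category | str = Category.WT,
) -> EnrichmentResult:
    """Fisher co-occurrence/mutual-exclusivity test of one co-driver gene
    in an FGFR2 category versus reference (WT) samples.

    OR > 1 indicates co-occurrence, OR < 1 mutual exclusivity.  When any
    cell is zero all cells get +0.5 before the OR and its Woolf CI.
    """
    category = Category(category)
    reference = Category(reference)
    cats = categories.loc[matrix.index].astype(str)
    focal = cats == category.value
    ref = cats == reference.value
    altered = matrix[gene].astype(bool)
    a = int((focal & altered).sum())
    b = int((focal & ~altered).sum())
    c = int((ref & altered).sum())
    d = int((ref & ~altered).sum())
    p = fisher_exact_two_sided(a, b, c, d)
    cells = np.array([a, b, c, d], dtype=float)
    if (cells == 0).any():
        cells = cells + 0.5
    aa, bb, cc, dd = cells
    odds = (aa * dd) / (bb * cc)
    se_log = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    ci_low = float(np.exp(np.log(odds) - 1.959963984540054 * se_log))
    ci_high = float(np.exp(np.log(odds) + 1.959963984540054 * se_log))
    return EnrichmentResult(
        gene=gene, category=category.value, a=a, b=b, c=c, d=d,
        odds_ratio=float(odds), ci_low=ci_low, ci_high=ci_high, p_fisher=p,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_enrichment(
    matrix: pd.DataFrame,
    categories: pd.Series,
    *,
    genes: list[str] | None = None,
    z_mode: str = "within_altered",
) -> pd.DataFrame:
    """Full enrichment table: proportion-Z enrichment per altered category
    (focal versus the other two altered categories, or versus all other
    samples with ``z_mode='vs_all'``) and Fisher category-versus-WT
    co-occurrence, each BH-adjusted within its (test x category) family.
    """
    if z_mode not in ("within_altered", "vs_all"):
        raise ValueError("z_mode must be 'within_altered' or 'vs_all'")
    genes = list(matrix.columns) if genes is None else list(genes)
    cats = categories.loc[matrix.index].astype(str)

    rows = []
    for cat in ALTERED_CATEGORIES:
        focal = cats == cat.value
        if z_mode == "within_altered":
            other = cats.isin([c.value for c in ALTERED_CATEGORIES if c is not cat])
        else:
            other = ~focal
        n1, n2 = int(focal.sum()), int(other.sum())
        z_results = []
        fisher_results = []
        for g in genes:
            altered = matrix[g].astype(bool)
            x1 = int((focal & altered).sum())
            x2 = int((other & altered).sum())
            if n1 > 0 and n2 > 0:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    z, p_z = proportion_z_enrichment(x1, n1, x2, n2)
            else:
                z, p_z = 0.0, 1.0
            z_results.append((g, x1, n1 - x1, x2, n2 - x2, z, p_z))
            fisher_results.append(fisher_cooccurrence(matrix, categories, g, cat))
        q_z = bh_adjust([r[6] for r in z_results])
        q_f = bh_adjust([r.p_fisher for r in fisher_results])
        for (g, a, b, c, d, z, p_z), fr, qz, qf in zip(z_results, fisher_results, q_z, q_f):
            rows.append(
                {
                    "gene": g, "category": cat.value,
                    "z_a": a, "z_b": b, "z_c": c, "z_d": d,
                    "proportion_z": z, "p_z": p_z, "q_z": qz,
                    "a": fr.a, "b": fr.b, "c": fr.c, "d": fr.d,
                    "odds_ratio": fr.odds_ratio,
                    "ci_low": fr.ci_low, "ci_high": fr.ci_high,
                    "p_fisher": fr.p_fisher, "q_fisher": qf,
                }
            )
    return pd.DataFrame(rows)
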