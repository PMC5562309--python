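"""RP-mutation stratification and the gene-wise co-mutation screen.

Tumors split into RP-mutant (>= 1 non-silent mutation in any RP gene) and
non-RP-mutant groups.  For every other gene with at least one mutation
anywhere, a 2x2 Pearson chi-squared test (no continuity correction) asks
whether its mutation frequency differs between the two groups; the family
is corrected with Bonferroni over the tested genes (BH available as an
alternative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import GeneSet, MutationTable
from .diffstats import bh_adjust

__all__ = ["MutationScreenResult", "rp_mutation_status", "genewise_chi2_screen"]


@dataclass(frozen=True)
class MutationScreenResult:
    gene: str
    count_in_rpmut: int
    n_rpmut: int
    count_in_nonrpmut: int
    n_nonrpmut: int
    chi2: float
    p: float
    p_adjusted: float
    significant: bool
    low_expected: bool  # some expected cell count < 5


def rp_mutation_status(mutations: MutationTable, rp_genes: GeneSet) -> dict[str, bool]:
    """True for samples with >= 1 non-silent mutation in any RP gene."""
    rp = set(rp_genes.genes)
    return {s: mutations.has_mutation(s, rp) for s in mutations.samples}


def _chi2_2x2(a: float, b: float, c: float, d: float):
    """Pearson chi-squared for the 2x2 table [[a, b], [c, d]], uncorrected.

    Closed form N(ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)).  A zero margin makes
    the statistic 0/0; those tables carry no information and get chi2 = 0.
    """
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0, 1.0
    chi2 = n * (a * d - b * c) ** 2 / denom
    return chi2, float(stats.chi2.sf(chi2, df=1))


def genewise_chi2_screen(
    mutations: MutationTable,
    status: dict[str, bool],
    rp_genes: GeneSet | None = None,
    alpha: float = 0.05,
    correction: str = "bonferroni",
) -> list[MutationScreenResult]:
    """Screen non-RP genes for differential mutation frequency by RP status.

    Only genes with >= 1 mutation anywhere enter the screen, and the
    multiple-testing family size m is the number of genes tested.
    ``correction`` is "bonferroni" (default) or "bh".
    """
    rp = set(rp_genes.genes) if rp_genes is not None else set()
    rpmut = [s for s in mutations.samples if status[s]]
    nonrp = [s for s in mutations.samples if not status[s]]
    if not rpmut or not nonrp:
        raise ValueError("both the RP-mutant and non-RP-mutant strata must be non-empty")
    n1, n2 = len(rpmut), len(nonrp)
    genes = [g for g in mutations.genes if g not in rp]
    raw = []
    for gene in genes:
        a = sum(1 for s in rpmut if gene in mutations.mutated_genes(s))
        c = sum(1 for s in nonrp if gene in mutations.mutated_genes(s))
        if a + c == 0:
            continue  # unmutated anywhere: outside the tested family
        b, d = n1 - a, n2 - c
        chi2, p = _chi2_2x2(a, b, c, d)
        n = n1 + n2
        expected_min = min(
            (a + c) * n1 / n, (a + c) * n2 / n, (b + d) * n1 / n, (b + d) * n2 / n
        )
        raw.append((gene, a, c, chi2, p, expected_min < 5))
    m = len(raw)
    if correction == "bonferroni":
        adjusted = [min(1.0, r[4] * m) for r in raw]
        significant = [padj < alpha for padj in adjusted]
    elif correction == "bh":
        q, sig = bh_adjust([r[4] for r in raw], alpha)
        adjusted, significant = list(q), list(sig)
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return [
        MutationScreenResult(
            gene=gene,
            count_in_rpmut=a,
            n_rpmut=n1,
            count_in_nonrpmut=c,
            n_nonrpmut=n2,
            chi2=chi2,
            p=p,
            p_adjusted=float(padj),
            significant=bool(sig),
            low_expected=bool(low),
        )
        for (gene, a, c, chi2, p, low), padj, sig in zip(raw, adjusted, significant)
    ]
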