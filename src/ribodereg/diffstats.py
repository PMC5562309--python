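"""Grouped per-gene differential statistics.

Two families of tests run on percent-of-pool relative expression:

* Welch (unequal-variance) two-sided t-tests between two sample groups,
  with Benjamini–Hochberg control at a chosen FDR — the mouse-model design
  (control hepatocytes/livers vs tumors);
* per-gene variance-ratio F-tests between matched tumors and normals —
  the matched-cohort design, asking whether a transcript's relative
  expression is more variable in tumors than in normal tissue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneTestResult",
    "welch_t_per_gene",
    "bh_adjust",
    "welch_test_table",
    "variance_f_test",
    "variance_f_table",
    "directionality_overlap",
]


@dataclass(frozen=True)
class GeneTestResult:
    gene: str
    statistic: float
    p: float
    q: float
    significant: bool
    direction: str  # "up", "down" or "none", for group B relative to group A


def welch_t_per_gene(rel_a: pd.DataFrame, rel_b: pd.DataFrame) -> pd.DataFrame:
    """Per-gene Welch t-test (two-sided, Welch–Satterthwaite df).

    ``rel_a`` and ``rel_b`` are gene-by-sample blocks with identical gene
    order.  Returns a frame indexed by gene with columns t, p, direction;
    direction is the sign of mean(B) − mean(A).  Genes constant and equal in
    both groups get t = 0, p = 1.
    """
    if list(rel_a.index) != list(rel_b.index):
        raise ValueError("gene sets of the two groups differ")
    if rel_a.shape[1] < 2 or rel_b.shape[1] < 2:
        raise ValueError("each group needs >= 2 samples")
    a, b = rel_a.to_numpy(dtype=float), rel_b.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    diff = b.mean(axis=1) - a.mean(axis=1)
    # both groups constant: scipy yields nan; equal means -> null, unequal
    # means -> infinitely strong separation
    degenerate = ~np.isfinite(t)
    with np.errstate(invalid="ignore"):
        t = np.where(degenerate, np.where(diff == 0, 0.0, np.inf * np.sign(-diff)), t)
        p = np.where(degenerate, np.where(diff == 0, 1.0, 0.0), p)
    direction = np.where(diff > 0, "up", np.where(diff < 0, "down", "none"))
    return pd.DataFrame({"t": t, "p": p, "direction": direction}, index=rel_a.index)


def bh_adjust(pvalues, fdr: float = 0.05):
    """Benjamini–Hochberg step-up q-values; significant means q < fdr."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size and ((p < 0).any() or (p > 1).any()):
        raise ValueError("P-values must lie in [0, 1]")
    if not 0 < fdr < 1:
        raise ValueError("fdr must lie in (0, 1)")
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q, q < fdr


def welch_test_table(
    rel_a: pd.DataFrame, rel_b: pd.DataFrame, fdr: float = 0.05
) -> list[GeneTestResult]:
    """Welch tests plus BH adjustment, as a list of per-gene results."""
    raw = welch_t_per_gene(rel_a, rel_b)
    q, sig = bh_adjust(raw["p"].to_numpy(), fdr)
    return [
        GeneTestResult(
            gene=str(g),
            statistic=float(raw.at[g, "t"]),
            p=float(raw.at[g, "p"]),
            q=float(q[i]),
            significant=bool(sig[i]),
            direction=str(raw.at[g, "direction"]),
        )
        for i, g in enumerate(raw.index)
    ]


def variance_f_test(tumor_values, normal_values, two_sided: bool = True):
    """Variance-ratio F-test for one transcript.

    F = s²_tumor / s²_normal with (n_t−1, n_n−1) degrees of freedom.  The
    two-sided P is 2·min(lower tail, upper tail) capped at 1; one-sided
    (variance greater in tumors) is the upper tail only.  Returns
    (F, p, flag) where flag marks degenerate variance cases.
    """
    t = np.asarray(list(tumor_values), dtype=float)
    n = np.asarray(list(normal_values), dtype=float)
    if t.size < 2 or n.size < 2:
        raise ValueError("need >= 2 values on each side")
    s2_t = t.var(ddof=1)
    s2_n = n.var(ddof=1)
    if s2_t == 0 and s2_n == 0:
        return np.nan, np.nan, "both_zero_variance"
    if s2_n == 0:
        return np.inf, 0.0, "normal_zero_variance"
    f = s2_t / s2_n
    d1, d2 = t.size - 1, n.size - 1
    if two_sided:
        cdf = stats.f.cdf(f, d1, d2)
        p = min(1.0, 2.0 * min(cdf, 1.0 - cdf))
    else:
        p = stats.f.sf(f, d1, d2)
    return float(f), float(p), ""


def variance_f_table(
    rel_tumors: pd.DataFrame,
    rel_normals: pd.DataFrame,
    fdr: float = 0.05,
    two_sided: bool = True,
) -> pd.DataFrame:
    """Per-gene F-tests with BH adjustment over the testable genes.

    Genes with zero variance on both sides are reported untestable
    (F, p, q = NaN, flag set) and excluded from the BH family.
    """
    if list(rel_tumors.index) != list(rel_normals.index):
        raise ValueError("gene sets of the two matrices differ")
    rows = []
    for g in rel_tumors.index:
        f, p, flag = variance_f_test(
            rel_tumors.loc[g].to_numpy(), rel_normals.loc[g].to_numpy(), two_sided=two_sided
        )
        rows.append((g, f, p, flag))
    table = pd.DataFrame(rows, columns=["gene", "F", "p", "flag"]).set_index("gene")
    testable = table["p"].notna()
    q = np.full(len(table), np.nan)
    sig = np.zeros(len(table), dtype=bool)
    if testable.any():
        q_t, sig_t = bh_adjust(table.loc[testable, "p"].to_numpy(), fdr)
        q[testable.to_numpy()] = q_t
        sig[testable.to_numpy()] = sig_t
    table["q"] = q
    table["significant"] = sig
    return table


def directionality_overlap(results_a, results_b) -> pd.Series:
    """Classify each gene's significance pattern across two comparisons.

    Labels: both_same_direction, both_opposite_direction, only_A, only_B,
    neither.  The labels partition the gene set.
    """
    genes_a = [r.gene for r in results_a]
    genes_b = [r.gene for r in results_b]
    if genes_a != genes_b:
        raise ValueError("the two result lists cover different gene sets")
    labels = {}
    for ra, rb in zip(results_a, results_b):
        if ra.significant and rb.significant:
            if ra.direction == rb.direction:
                labels[ra.gene] = "both_same_direction"
            else:
                labels[ra.gene] = "both_opposite_direction"
        elif ra.significant:
            labels[ra.gene] = "only_A"
        elif rb.significant:
            labels[ra.gene] = "only_B"
        else:
            labels[ra.gene] = "neither"
    return pd.Series(labels, name="overlap")
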