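"""Percent-of-pool relative expression and the normal-tissue reference.

Each sample's summed abundance over the RP gene set is set to 100%, so a
gene's value is its share of the RP transcript pool in that sample.  This
removes per-sample sequencing depth and overall RP induction, leaving only
stoichiometry.  Group profiles average these per-sample shares; the normal
reference summarizes them as a per-gene mean and standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, GeneSet, warn_data

__all__ = [
    "RelativeExpressionMatrix",
    "GroupProfile",
    "NormalReference",
    "relative_percent",
    "group_profiles",
    "normal_reference",
    "percent_deviation_map",
    "order_by_reference",
]

#: Lowest-abundance transcripts excluded from human deviation area maps to
#: keep the plot scale readable (their relative variability dwarfs the rest).
DEFAULT_AREA_MAP_EXCLUDE = ("Rps26", "Rpl9", "Rps27", "Rps28", "Rpl21")


class RelativeExpressionMatrix:
    """Gene-by-sample percent-of-pool values; every column sums to 100."""

    #: relative tolerance on the column-sum invariant
    COLUMN_SUM_RTOL = 1e-9

    def __init__(self, gene_set: GeneSet, rel: pd.DataFrame, groups) -> None:
        rel = rel.astype(float)
        if list(rel.index) != list(gene_set.genes):
            raise ValueError("rows must equal the gene set, in order")
        values = rel.to_numpy()
        if values.size:
            if (values < 0).any() or (values > 100).any():
                raise ValueError("relative expression values must lie in [0, 100]")
            sums = values.sum(axis=0)
            if not np.allclose(sums, 100.0, rtol=self.COLUMN_SUM_RTOL, atol=0):
                bad = rel.columns[np.argmax(np.abs(sums - 100.0))]
                raise ValueError(f"column {bad!r} does not sum to 100 (got {sums.max()!r})")
        groups = dict(groups)
        missing = [s for s in rel.columns if s not in groups]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        self.gene_set = gene_set
        self.rel = rel
        self.groups = {s: str(groups[s]) for s in rel.columns}

    @property
    def genes(self) -> tuple[str, ...]:
        return self.gene_set.genes

    @property
    def samples(self) -> list[str]:
        return list(self.rel.columns)

    @property
    def values(self) -> np.ndarray:
        return self.rel.to_numpy()

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.samples if self.groups[s] == group]

    def subset_samples(self, samples) -> "RelativeExpressionMatrix":
        samples = list(samples)
        unknown = [s for s in samples if s not in self.rel.columns]
        if unknown:
            raise KeyError(f"unknown samples: {unknown}")
        return RelativeExpressionMatrix(
            self.gene_set, self.rel.loc[:, samples], {s: self.groups[s] for s in samples}
        )

    def __repr__(self) -> str:
        return (
            f"<RelativeExpressionMatrix {len(self.gene_set)} genes x {len(self.samples)} samples>"
        )


@dataclass(frozen=True)
class GroupProfile:
    """Average percent contribution of each gene within one sample group."""

    group: str
    mean_rel: pd.Series
    n_samples: int


@dataclass(frozen=True)
class NormalReference:
    """Per-gene mean (mu) and sample SD (sigma) of relative expression in normals."""

    gene_set: GeneSet
    mu: pd.Series
    sigma: pd.Series
    n_normals: int

    def __post_init__(self) -> None:
        if (self.sigma < 0).any():
            raise ValueError("sigma must be nonnegative")


def relative_percent(matrix: ExpressionMatrix) -> RelativeExpressionMatrix:
    """Convert abundances to percent of the per-sample gene-set pool.

    rel[g, s] = 100 * value[g, s] / sum_g' value[g', s].  Invariant under any
    per-sample rescaling of the raw column.
    """
    totals = matrix.data.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(
            f"sample(s) with zero total gene-set abundance: {list(zero.index)}"
        )
    rel = matrix.data.div(totals, axis=1) * 100.0
    return RelativeExpressionMatrix(matrix.gene_set, rel, matrix.groups)


def group_profiles(rel: RelativeExpressionMatrix) -> list[GroupProfile]:
    """Per-group arithmetic mean of per-sample relative values.

    Normalization happens per sample first, averaging second, so matched- and
    unmatched-sample analyses see the same per-sample quantities.
    """
    profiles = []
    for group in sorted(set(rel.groups.values())):
        cols = rel.samples_in_group(group)
        mean = rel.rel.loc[:, cols].mean(axis=1)
        profiles.append(GroupProfile(group, mean, len(cols)))
    return profiles


def normal_reference(rel_normals: RelativeExpressionMatrix) -> NormalReference:
    """Per-gene mean and sample SD (ddof=1) across normal samples."""
    n = len(rel_normals.samples)
    if n < 2:
        raise ValueError(f"need >= 2 normal samples to build a reference, got {n}")
    mu = rel_normals.rel.mean(axis=1)
    sigma = rel_normals.rel.std(axis=1, ddof=1)
    return NormalReference(rel_normals.gene_set, mu, sigma, n)


def percent_deviation_map(
    rel_tumors: RelativeExpressionMatrix,
    reference: NormalReference,
    exclude=None,
) -> pd.DataFrame:
    """Percent difference from the normal mean, per gene and sample.

    dev[g, s] = 100 * (rel[g, s] - mu[g]) / mu[g].  Rows named in ``exclude``
    are dropped from the returned grid only; genes with mu = 0 are kept as
    NaN rows with a warning.
    """
    if rel_tumors.gene_set.genes != reference.gene_set.genes:
        raise ValueError("gene sets of matrix and reference differ")
    exclude = set(exclude or ())
    unknown = exclude - set(rel_tumors.genes)
    if unknown:
        raise ValueError(f"exclude list names unknown genes: {sorted(unknown)}")
    mu = reference.mu
    with np.errstate(divide="ignore", invalid="ignore"):
        dev = rel_tumors.rel.sub(mu, axis=0).div(mu, axis=0) * 100.0
    zero_mu = mu.index[mu == 0].difference(pd.Index(exclude))
    if len(zero_mu):
        dev.loc[zero_mu] = np.nan
        warn_data(
            f"deviation undefined (mu=0) for gene(s): {', '.join(zero_mu)}; emitted as NA"
        )
    keep = [g for g in rel_tumors.genes if g not in exclude]
    return dev.loc[keep]


def order_by_reference(profiles, reference_group: str):
    """Order genes by descending abundance in the reference group's profile.

    Returns (ordered gene list, profiles reordered identically).  Ties break
    by ascending gene symbol.  This is the heat-map row order: every group is
    listed in the control group's order.
    """
    by_group = {p.group: p for p in profiles}
    if reference_group not in by_group:
        raise ValueError(f"reference group {reference_group!r} not among profiles")
    ref = by_group[reference_group].mean_rel
    order = sorted(ref.index, key=lambda g: (-ref[g], g))
    reordered = [
        GroupProfile(p.group, p.mean_rel.loc[order], p.n_samples) for p in profiles
    ]
    return order, reordered
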