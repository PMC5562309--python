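"""Core data containers shared by every stage of the pipeline.

The analysis universe is a small, ordered gene set (the ~80 cytoplasmic
ribosomal-protein genes).  Everything downstream — percent-of-pool
normalization, the normal-tissue reference, per-tumor deregulation
profiles — inherits the gene order fixed here, so the containers enforce
it once and the numerical code never re-checks it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RibodergWarning",
    "GeneSet",
    "ExpressionMatrix",
    "SurvivalRecord",
    "MutationTable",
]


class RibodergWarning(UserWarning):
    """Warning channel for recoverable data issues (missing genes, zero-mean rows)."""


@dataclass(frozen=True)
class GeneSet:
    """An ordered, duplicate-free collection of gene symbols.

    The order is canonical: every matrix, profile and reference built from
    this set lists genes in exactly this order.
    """

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        genes = tuple(str(g) for g in self.genes)
        if not genes:
            raise ValueError("GeneSet must contain at least one gene")
        if len(set(genes)) != len(genes):
            dupes = sorted({g for g in genes if list(genes).count(g) > 1})
            raise ValueError(f"duplicate gene symbols in GeneSet {self.name!r}: {dupes}")
        object.__setattr__(self, "genes", genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)

    def index(self) -> pd.Index:
        return pd.Index(self.genes, name="gene")


class ExpressionMatrix:
    """Nonnegative abundance values for a gene set across samples.

    Parameters
    ----------
    gene_set : GeneSet
        Canonical row order.
    data : pandas.DataFrame
        Genes (rows, in ``gene_set`` order) by samples (columns).  Units are
        whatever the upstream quantification produced (counts, RSEM, FPKM);
        percent-of-pool normalization removes per-sample scale.
    groups : mapping of sample id -> group label
        Exactly one label per sample (e.g. "normal" / "tumor").
    """

    def __init__(self, gene_set: GeneSet, data: pd.DataFrame, groups) -> None:
        data = data.astype(float)
        if list(data.index) != list(gene_set.genes):
            raise ValueError("data rows must equal the gene set, in order")
        if data.columns.duplicated().any():
            raise ValueError("duplicate sample IDs")
        values = data.to_numpy()
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite value at gene {data.index[bad[0]]!r}, "
                f"sample {data.columns[bad[1]]!r}"
            )
        if (values < 0).any():
            bad = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative value at gene {data.index[bad[0]]!r}, "
                f"sample {data.columns[bad[1]]!r}"
            )
        groups = dict(groups)
        missing = [s for s in data.columns if s not in groups]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        self.gene_set = gene_set
        self.data = data
        self.groups = {s: str(groups[s]) for s in data.columns}

    @property
    def genes(self) -> tuple[str, ...]:
        return self.gene_set.genes

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.samples if self.groups[s] == group]

    def subset_samples(self, samples) -> "ExpressionMatrix":
        samples = list(samples)
        unknown = [s for s in samples if s not in self.data.columns]
        if unknown:
            raise KeyError(f"unknown samples: {unknown}")
        return ExpressionMatrix(
            self.gene_set,
            self.data.loc[:, samples],
            {s: self.groups[s] for s in samples},
        )

    def __repr__(self) -> str:
        return (
            f"<ExpressionMatrix {len(self.gene_set)} genes x "
            f"{len(self.samples)} samples, groups={sorted(set(self.groups.values()))}>"
        )


@dataclass
class SurvivalRecord:
    """Time-to-event observation for one sample.

    ``event`` is True when the death/event was observed, False when the
    follow-up was censored at ``time``.  ``stratum`` is filled in by the
    stratification step (score quartile, mutation status).
    """

    sample_id: str
    time: float
    event: bool
    stratum: str = ""

    def __post_init__(self) -> None:
        self.time = float(self.time)
        if self.time < 0:
            raise ValueError(f"negative survival time for {self.sample_id!r}")
        if not isinstance(self.event, (bool, np.bool_)):
            raise ValueError(f"event flag for {self.sample_id!r} must be boolean")
        self.event = bool(self.event)


class MutationTable:
    """Binary non-silent mutation indicators over a sample universe.

    Samples in the universe with no recorded mutation are retained as
    mutation-free; duplicate (sample, gene) rows collapse to one indicator.
    """

    def __init__(self, entries, sample_universe) -> None:
        universe = [str(s) for s in sample_universe]
        if len(set(universe)) != len(universe):
            raise ValueError("duplicate sample IDs in sample universe")
        uni = set(universe)
        collapsed: set[tuple[str, str]] = set()
        for sample_id, gene in entries:
            sample_id, gene = str(sample_id), str(gene)
            if sample_id not in uni:
                raise ValueError(f"mutation entry for sample {sample_id!r} not in universe")
            collapsed.add((sample_id, gene))
        self.samples = universe
        self.entries = sorted(collapsed)
        self._by_sample: dict[str, set[str]] = {s: set() for s in universe}
        for sample_id, gene in self.entries:
            self._by_sample[sample_id].add(gene)

    @property
    def genes(self) -> list[str]:
        """All genes with at least one non-silent mutation, sorted."""
        return sorted({g for _, g in self.entries})

    def mutated_genes(self, sample_id: str) -> frozenset[str]:
        return frozenset(self._by_sample[sample_id])

    def has_mutation(self, sample_id: str, genes) -> bool:
        return not self._by_sample[sample_id].isdisjoint(set(genes))

    def __len__(self) -> int:
        return len(self.entries)

    def __repr__(self) -> str:
        return f"<MutationTable {len(self.entries)} entries across {len(self.samples)} samples>"


def warn_data(message: str) -> None:
    """Emit a recoverable data warning on the package warning channel."""
    warnings.warn(message, RibodergWarning, stacklevel=3)
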