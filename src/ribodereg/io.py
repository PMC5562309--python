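"""Readers and writers for the pipeline's tab-separated formats.

All tables are UTF-8 TSV with a header row.  Gene symbols match
case-sensitively and verbatim, mirroring common RNA-seq matrix exports.
"""

from __future__ import annotations

import csv
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, GeneSet, MutationTable, SurvivalRecord, warn_data

__all__ = [
    "DEFAULT_NONSILENT",
    "load_default_rp_genes",
    "read_gene_set",
    "read_expression_table",
    "write_expression_table",
    "read_clinical_table",
    "read_mutation_table",
    "read_groups_table",
    "write_run_summary",
]

#: Variant classifications treated as non-silent (case-insensitive match).
DEFAULT_NONSILENT = frozenset(
    {
        "missense_mutation",
        "missense",
        "nonsense_mutation",
        "nonsense",
        "frame_shift_del",
        "frame_shift_ins",
        "frameshift",
        "splice_site",
        "splice",
        "in_frame_del",
        "in_frame_ins",
        "in_frame_indel",
        "nonstop_mutation",
        "translation_start_site",
    }
)


def load_default_rp_genes() -> GeneSet:
    """The packaged 77-gene human cytoplasmic RP set (RPS*/RPL*/RPLP*)."""
    text = resources.files("ribodereg").joinpath("data/human_rp_77.txt").read_text("utf-8")
    genes = [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    return GeneSet("human_rp_77", tuple(genes))


def read_gene_set(path, name: str | None = None) -> GeneSet:
    """Read one gene symbol per line; '#' lines are comments."""
    path = Path(path)
    genes = [
        ln.strip()
        for ln in path.read_text("utf-8").splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    return GeneSet(name or path.stem, tuple(genes))


def read_expression_table(path, gene_set: GeneSet, groups=None) -> ExpressionMatrix:
    """Read a gene-by-sample abundance TSV restricted to ``gene_set``.

    The first row holds sample IDs, the first column gene symbols.  Genes in
    the gene set but absent from the file are filled with 0 (with a warning);
    file genes outside the set are dropped.  Samples without an entry in
    ``groups`` are labelled ``"all"``.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows or len(rows[0]) < 2:
        raise ValueError(f"{path}: expected a header row with at least one sample")
    header = rows[0]
    samples = [s.strip() for s in header[1:]]
    if len(set(samples)) != len(samples):
        raise ValueError(f"{path}: duplicate sample IDs in header")
    n_fields = len(header)
    parsed: dict[str, list[float]] = {}
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != n_fields:
            raise ValueError(f"{path}: line {i} has {len(row)} fields, expected {n_fields}")
        gene = row[0].strip()
        vals = []
        for j, tok in enumerate(row[1:]):
            try:
                v = float(tok)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric value {tok!r} at gene {gene!r}, sample {samples[j]!r}"
                ) from None
            if not np.isfinite(v) or v < 0:
                raise ValueError(
                    f"{path}: invalid value {tok!r} at gene {gene!r}, sample {samples[j]!r}"
                    " (must be finite and >= 0)"
                )
            vals.append(v)
        parsed[gene] = vals

    matched = [g for g in gene_set.genes if g in parsed]
    if not matched:
        raise ValueError(f"{path}: no genes of set {gene_set.name!r} found in file")
    missing = [g for g in gene_set.genes if g not in parsed]
    if missing:
        warn_data(
            f"{path}: {len(missing)} gene(s) of set {gene_set.name!r} absent from file, "
            f"filled with 0: {', '.join(missing)}"
        )
    data = pd.DataFrame(
        [parsed.get(g, [0.0] * len(samples)) for g in gene_set.genes],
        index=gene_set.index(),
        columns=samples,
    )
    if groups is None:
        groups = {s: "all" for s in samples}
    return ExpressionMatrix(gene_set, data, groups)


def write_expression_table(matrix, path) -> None:
    """Write a gene-by-sample TSV (works for raw or relative matrices).

    Values are formatted with ``repr`` so a write/read/write cycle is
    text-identical.
    """
    data = matrix.data if hasattr(matrix, "data") else matrix
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["gene", *data.columns])
        for gene, row in data.iterrows():
            writer.writerow([gene, *(repr(float(v)) for v in row)])


def read_clinical_table(path) -> list[SurvivalRecord]:
    """Read sample_id / time / event (0=censored, 1=event) records."""
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "time", "event"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}, got {list(df.columns)}")
    dupes = df["sample_id"][df["sample_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"{path}: duplicate sample IDs: {sorted(set(dupes))}")
    records = []
    for _, row in df.iterrows():
        time = float(row["time"])
        if time < 0:
            raise ValueError(f"{path}: negative time for sample {row['sample_id']!r}")
        ev = row["event"].strip()
        if ev not in {"0", "1"}:
            raise ValueError(
                f"{path}: event for sample {row['sample_id']!r} must be 0 or 1, got {ev!r}"
            )
        records.append(SurvivalRecord(row["sample_id"], time, ev == "1"))
    return records


def read_mutation_table(path, sample_universe, nonsilent=DEFAULT_NONSILENT) -> MutationTable:
    """Read sample_id / gene / classification rows into binary indicators.

    Rows whose classification is not in the non-silent whitelist are dropped;
    samples in the universe without rows stay in the table as mutation-free.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    nonsilent = {c.lower() for c in nonsilent}
    universe = [str(s) for s in sample_universe]
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "gene", "classification"}
    if len(df) and not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}, got {list(df.columns)}")
    entries = []
    if len(df):
        keep = df["classification"].str.strip().str.lower().isin(nonsilent)
        for _, row in df[keep].iterrows():
            entries.append((row["sample_id"].strip(), row["gene"].strip()))
    return MutationTable(entries, universe)


def read_groups_table(path) -> dict[str, str]:
    """Read a two-column sample_id -> label TSV (used for strata and groups)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (sample_id, label)")
    ids, labels = df.iloc[:, 0], df.iloc[:, 1]
    if ids.duplicated().any():
        raise ValueError(f"{path}: duplicate sample IDs")
    return dict(zip(ids.str.strip(), labels.str.strip()))


def write_run_summary(path, summary: dict) -> None:
    """Write a machine-readable key<TAB>value run summary."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for key, value in summary.items():
            fh.write(f"{key}\t{value}\n")
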