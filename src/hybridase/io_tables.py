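"""Strict TSV readers and writers for every table the pipeline touches.

Conventions: tab-separated, UTF-8, Unix newlines, ``.`` decimal.  Count
tables are wide, with a ``gene_id`` column followed by one
``<sample>__<ortholog>`` column per (sample, ortholog) pair.  Readers
reject malformed input rather than coercing it; writers are deterministic
(genes lexicographic, samples in metadata order) so files are diffable and
round-trips are byte-identical.
"""
from __future__ import annotations

from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd

from .config import GROUPS

__all__ = [
    "SchemaError",
    "read_counts",
    "write_counts",
    "read_metadata",
    "write_metadata",
    "read_ortholog_map",
    "write_ortholog_map",
    "read_truth",
    "write_truth",
    "read_results",
    "write_results",
    "validate_counts",
    "check_samples_match",
]

ORTHOLOGS = ("species1", "species2")

METADATA_COLUMNS = ["sample_id", "group", "tissue", "stage", "replicate"]
ORTHOLOG_MAP_COLUMNS = ["unified_gene_id", "species1_gene_id", "species2_gene_id"]
RESULT_COLUMNS = [
    "gene_id",
    "stratum",
    "log2fc_dge",
    "p_dge",
    "padj_dge",
    "log2fc_ase",
    "p_ase",
    "padj_ase",
    "category",
]
TRUTH_COLUMNS = ["gene_id", "architecture", "c", "t", "expected_dge", "expected_ase"]

# 12 significant digits: floats survive a write/read cycle at the precision
# any downstream comparison cares about.
FLOAT_FORMAT = "%.12g"


class SchemaError(ValueError):
    """A table violates its schema (named row/column in the message)."""


def _read_tsv(path: Union[str, Path]) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - message passthrough
        raise SchemaError(f"cannot parse {path}: {exc}") from exc


def validate_counts(counts: pd.DataFrame) -> None:
    """Check the in-memory count-table contract."""
    if counts.index.has_duplicates:
        dups = counts.index[counts.index.duplicated()].unique().tolist()
        raise SchemaError(f"duplicate gene_id rows: {dups[:5]}")
    if counts.columns.nlevels != 2:
        raise SchemaError("count table needs (sample, ortholog) columns")
    samples = counts.columns.get_level_values(0).unique()
    for s in samples:
        present = set(counts[s].columns)
        missing = set(ORTHOLOGS) - present
        if missing:
            raise SchemaError(
                f"sample {s!r} is missing ortholog column(s) {sorted(missing)}"
            )
    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        raise SchemaError("counts must be integers")
    if (values < 0).any():
        bad = counts.index[(values < 0).any(axis=1)][0]
        raise SchemaError(f"negative count in gene {bad!r}")


def read_counts(path: Union[str, Path]) -> pd.DataFrame:
    """Read an allele-resolved count table.

    The header is ``gene_id`` followed by ``<sample>__<ortholog>`` columns;
    every sample must have both ortholog columns and every cell must be a
    non-negative integer (zeros written explicitly, no missing values).
    """
    raw = _read_tsv(path)
    if raw.columns[0] != "gene_id":
        raise SchemaError(
            f"{path}: first column must be 'gene_id', got {raw.columns[0]!r}"
        )
    tuples = []
    for col in raw.columns[1:]:
        parts = col.rsplit("__", 1)
        if len(parts) != 2 or parts[1] not in ORTHOLOGS:
            raise SchemaError(
                f"{path}: column {col!r} is not '<sample>__<ortholog>' with "
                f"ortholog in {list(ORTHOLOGS)}"
            )
        tuples.append((parts[0], parts[1]))
    if raw["gene_id"].duplicated().any():
        dup = raw["gene_id"][raw["gene_id"].duplicated()].iloc[0]
        raise SchemaError(f"{path}: duplicate gene_id {dup!r}")
    body = raw.iloc[:, 1:]
    for col in body.columns:
        vals = body[col]
        bad = ~vals.str.fullmatch(r"\d+")
        if bad.any():
            gene = raw["gene_id"][bad].iloc[0]
            raise SchemaError(
                f"{path}: column {col!r}, gene {gene!r}: "
                f"{vals[bad].iloc[0]!r} is not a non-negative integer"
            )
    counts = body.astype(np.int64)
    counts.index = pd.Index(raw["gene_id"], name="gene_id")
    counts.columns = pd.MultiIndex.from_tuples(tuples, names=["sample", "ortholog"])
    validate_counts(counts)
    return counts


def write_counts(counts: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a count table in canonical form: genes sorted lexicographically,
    columns in the table's (metadata) sample order."""
    validate_counts(counts)
    out = counts.sort_index()
    flat = out.copy()
    flat.columns = [f"{s}__{o}" for s, o in out.columns]
    flat.to_csv(path, sep="\t", lineterminator="\n")


def read_metadata(path: Union[str, Path]) -> pd.DataFrame:
    raw = _read_tsv(path)
    missing = [c for c in METADATA_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: metadata is missing column(s) {missing}")
    meta = raw[METADATA_COLUMNS].copy()
    if meta["sample_id"].duplicated().any():
        dup = meta["sample_id"][meta["sample_id"].duplicated()].iloc[0]
        raise SchemaError(f"{path}: duplicate sample_id {dup!r}")
    bad = ~meta["group"].isin(GROUPS)
    if bad.any():
        raise SchemaError(
            f"{path}: sample {meta['sample_id'][bad].iloc[0]!r} has group "
            f"{meta['group'][bad].iloc[0]!r}; allowed groups: {list(GROUPS)}"
        )
    if not meta["replicate"].str.fullmatch(r"\d+").all():
        raise SchemaError(f"{path}: replicate must be a non-negative integer")
    meta["replicate"] = meta["replicate"].astype(int)
    return meta


def write_metadata(meta: pd.DataFrame, path: Union[str, Path]) -> None:
    meta[METADATA_COLUMNS].to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_ortholog_map(path: Union[str, Path]) -> pd.DataFrame:
    raw = _read_tsv(path)
    missing = [c for c in ORTHOLOG_MAP_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: ortholog map is missing column(s) {missing}")
    omap = raw[ORTHOLOG_MAP_COLUMNS].copy()
    for col in ORTHOLOG_MAP_COLUMNS:
        if omap[col].duplicated().any():
            dup = omap[col][omap[col].duplicated()].iloc[0]
            raise SchemaError(f"{path}: duplicate {col} {dup!r}")
    return omap


def write_ortholog_map(omap: pd.DataFrame, path: Union[str, Path]) -> None:
    omap[ORTHOLOG_MAP_COLUMNS].to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def read_truth(path: Union[str, Path]) -> pd.DataFrame:
    raw = _read_tsv(path)
    missing = [c for c in TRUTH_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: truth table is missing column(s) {missing}")
    truth = raw[TRUTH_COLUMNS].copy()
    for col in ("c", "t", "expected_dge", "expected_ase"):
        truth[col] = truth[col].astype(float)
    return truth


def write_truth(truth: pd.DataFrame, path: Union[str, Path]) -> None:
    truth[TRUTH_COLUMNS].to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FORMAT, lineterminator="\n"
    )


def write_results(results: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write per-gene regulatory results with a fixed, documented column
    order and 12-significant-digit floats."""
    missing = [c for c in RESULT_COLUMNS if c not in results.columns]
    if missing:
        raise SchemaError(f"results are missing column(s) {missing}")
    out = results[RESULT_COLUMNS].sort_values(["stratum", "gene_id"])
    out.to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FORMAT, lineterminator="\n"
    )


def read_results(path: Union[str, Path]) -> pd.DataFrame:
    raw = _read_tsv(path)
    missing = [c for c in RESULT_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: results are missing column(s) {missing}")
    res = raw[RESULT_COLUMNS].copy()
    float_cols = ["log2fc_dge", "p_dge", "padj_dge", "log2fc_ase", "p_ase", "padj_ase"]
    for col in float_cols:
        res[col] = pd.to_numeric(res[col].replace("", np.nan))
    for col in ("p_dge", "padj_dge", "p_ase", "padj_ase"):
        vals = res[col].dropna()
        if ((vals < 0) | (vals > 1)).any():
            raise SchemaError(f"{path}: {col} outside [0, 1]")
    return res


def check_samples_match(counts: pd.DataFrame, meta: pd.DataFrame) -> None:
    """Every sample in the count table has a metadata row and vice versa."""
    count_samples = set(counts.columns.get_level_values(0))
    meta_samples = set(meta["sample_id"])
    only_counts = sorted(count_samples - meta_samples)
    only_meta = sorted(meta_samples - count_samples)
    if only_counts or only_meta:
        raise SchemaError(
            f"sample mismatch: in counts only {only_counts[:5]}, "
            f"in metadata only {only_meta[:5]}"
        )
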