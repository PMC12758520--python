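"""Readers and writers for the pipeline's text formats.

Formats: GMT gene-set collections (name, description, tab-separated member
ids), tab-separated DE results tables (DESeq2-style column schema),
genes x samples count matrices, and one-id-per-line gene lists.  Gzip is
applied transparently when a path ends in ``.gz``.

Float dialect, pinned for byte-stable reruns and lossless round-trips:
"." decimal separator, no thousands separators, shortest-repr 17-significant-
digit formatting (``%.17g``), which renders values below 1e-4 in scientific
notation.  Missing values are written as ``NA``.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .enrich import ORA_REPORT_COLUMNS, GeneSetCollection
from .errors import ParseError, SchemaError
from .sdeg import DE_TABLE_COLUMNS

logger = logging.getLogger(__name__)


def _open_text(path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t", encoding="utf-8")
    return open(path, mode, encoding="utf-8")


def fmt_float(x) -> str:
    """Pinned float rendering: NA for missing, %.17g otherwise."""
    if pd.isna(x):
        return "NA"
    return f"{float(x):.17g}"


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, name TAB description TAB members.

    Duplicate member ids within a line are deduplicated with a warning;
    lines with fewer than three fields, or with no nonempty member field,
    are parse errors carrying the line number.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with _open_text(path, "r") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"expected >= 3 tab-separated fields, got {len(fields)}", lineno
                )
            name, description = fields[0], fields[1]
            members = [g.strip() for g in fields[2:] if g.strip()]
            if not members:
                raise ParseError(f"set {name!r} has no members", lineno)
            unique = list(dict.fromkeys(members))
            if len(unique) < len(members):
                warnings.warn(
                    f"{path}: line {lineno}: set {name!r} has "
                    f"{len(members) - len(unique)} duplicate member id(s); deduplicated"
                )
            if name in sets:
                raise ParseError(f"duplicate set name {name!r}", lineno)
            sets[name] = unique
            descriptions[name] = description
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with _open_text(path, "w") as fh:
        for name, members in collection.items():
            desc = collection.description(name)
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# DE tables
# ---------------------------------------------------------------------------

_REQUIRED_DE_COLUMNS = ("gene_id", "log2FoldChange", "padj")


def read_de_table(path) -> pd.DataFrame:
    """Read a tab-separated DE results table.

    Requires at least ``gene_id``, ``log2FoldChange`` and ``padj``; optional
    ``base_mean``, ``pvalue`` and ``stat`` columns are filled with NaN when
    absent.  Rows with NA ``padj`` are retained (DESeq2 emits them for
    independently filtered genes) but are ineligible for SS scoring — see
    :func:`ss_eligible`.  Duplicate gene ids are rejected.
    """
    table = pd.read_csv(path, sep="\t", na_values=["NA"])
    for col in _REQUIRED_DE_COLUMNS:
        if col not in table.columns:
            raise SchemaError(f"DE table {path} is missing mandatory column {col!r}")
    dup = table["gene_id"].duplicated()
    if dup.any():
        raise SchemaError(
            f"DE table {path} has duplicate gene_id(s), e.g. "
            f"{table.loc[dup, 'gene_id'].iloc[0]!r}"
        )
    table["gene_id"] = table["gene_id"].astype(str).str.strip()
    for col in DE_TABLE_COLUMNS:
        if col not in table.columns:
            table[col] = np.nan
    return table[DE_TABLE_COLUMNS]


def ss_eligible(de_table: pd.DataFrame) -> pd.Series:
    """Mask of rows with the non-missing padj and LFC needed for SS scoring."""
    return de_table["padj"].notna() & de_table["log2FoldChange"].notna()


def write_tsv(frame: pd.DataFrame, path) -> None:
    """Write a frame in the pinned tab-separated dialect."""
    out = frame.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(fmt_float)
        elif out[col].dtype == object:
            out[col] = out[col].map(
                lambda v: ";".join(map(str, v)) if isinstance(v, (list, tuple, set)) else v
            )
    with _open_text(path, "w") as fh:
        out.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def write_de_table(de_table: pd.DataFrame, path) -> None:
    write_tsv(de_table[DE_TABLE_COLUMNS], path)


def write_enrichment_report(report: pd.DataFrame, path) -> None:
    """Write an ORA report with the pinned column order."""
    write_tsv(report[ORA_REPORT_COLUMNS], path)


# ---------------------------------------------------------------------------
# count matrices and gene lists
# ---------------------------------------------------------------------------

def read_counts(path) -> pd.DataFrame:
    """Read a genes x samples count matrix (first column = gene ids)."""
    counts = pd.read_csv(path, sep="\t", index_col=0)
    if counts.shape[1] == 0:
        raise SchemaError(f"count matrix {path} has no sample columns")
    if counts.index.duplicated().any():
        raise SchemaError(f"count matrix {path} has duplicate gene ids")
    return counts


def write_counts(counts: pd.DataFrame, path) -> None:
    with _open_text(path, "w") as fh:
        counts.rename_axis("gene_id").to_csv(fh, sep="\t", lineterminator="\n")


def read_gene_list(path) -> list[str]:
    """Read a one-id-per-line gene list, trimming and dropping blank lines."""
    with _open_text(path, "r") as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes, path) -> None:
    with _open_text(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")
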