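"""Readers and writers for the tab-separated tables the tool consumes.

Three external formats are supported:

* DE result tables in the DESeq2 column dialect (``log2FoldChange``,
  ``pvalue``, ``padj``, ``baseMean``), normalised to the internal column
  names ``gene_id``, ``log_fc``, ``p_value``, ``adj_p``, ``base_mean``.
* Gene x tissue matrices (first column gene ids, header row tissue ids)
  holding either TPM expression values or genetic dosage variance (V^G)
  estimates. Missingness is explicit: the literal string ``NA`` (or an
  empty cell) on disk, ``NaN`` in memory — never silently coerced to 0.
* GMT gene-set files (set name, description, then member gene ids).

All tables are tab-separated with a header row; ``NA`` is emitted for
missing values on write so that a write/read round trip reproduces the
missingness pattern and values bit-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DE_COLUMNS",
    "GeneSetCollection",
    "read_de_table",
    "write_de_table",
    "read_matrix",
    "write_matrix",
    "read_gmt",
]

#: Missing-value markers accepted on read; "NA" is written on output.
NA_MARKERS = ("NA", "")

#: Internal DE table column order.
DE_COLUMNS = ["gene_id", "log_fc", "p_value", "adj_p", "base_mean"]

#: Column mapping for the DESeq2 results dialect.
_DESEQ2_MAP = {
    "log2FoldChange": "log_fc",
    "pvalue": "p_value",
    "padj": "adj_p",
    "baseMean": "base_mean",
}

#: Column names recognised as the gene identifier in DE tables.
_GENE_ID_NAMES = ("gene_id", "gene", "ensembl_gene_id", "row", "")


class ValidationError(ValueError):
    """A table violated a format or domain invariant."""


def _strip_version(gene_id: str) -> str:
    stem, _, suffix = gene_id.rpartition(".")
    if stem and suffix.isdigit():
        return stem
    return gene_id


def _numeric(series: pd.Series, path: Path, column: str) -> pd.Series:
    """Parse a string column to float, reporting the offending cell on failure."""
    cleaned = series.where(~series.isin(NA_MARKERS))
    try:
        # astype(float) round-trips the shortest decimal repr exactly
        return cleaned.astype(float)
    except (TypeError, ValueError):
        pass
    for row, value in enumerate(cleaned):
        if isinstance(value, str):
            try:
                float(value)
            except ValueError:
                raise ValidationError(
                    f"{path}: unparseable numeric value {value!r} "
                    f"in column {column!r}, data row {row + 1}"
                ) from None
    raise ValidationError(f"{path}: cannot parse column {column!r} as numeric")


def read_de_table(
    path: str | Path,
    dialect: str = "deseq2",
    strip_gene_versions: bool = False,
) -> pd.DataFrame:
    """Read a differential-expression result table.

    Parameters
    ----------
    path
        Tab-separated file with a header naming the gene id, log2 fold
        change, p-value and adjusted p-value columns of the dialect.
    dialect
        Only ``"deseq2"`` is supported.
    strip_gene_versions
        If True, trailing ``.N`` version suffixes are removed from gene
        identifiers (Ensembl versioned ids). Off by default.

    Returns
    -------
    pandas.DataFrame
        Columns ``gene_id, log_fc, p_value, adj_p, base_mean``; ``adj_p``
        and ``base_mean`` may contain NaN (missing).
    """
    if dialect != "deseq2":
        raise ValueError(f"unknown DE table dialect: {dialect!r}")
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)

    gene_col = None
    for name in _GENE_ID_NAMES:
        if name in raw.columns:
            gene_col = name
            break
    if gene_col is None:
        # DESeq2 results written with write.table carry gene ids as row
        # names in an unnamed (or arbitrary) first column.
        gene_col = raw.columns[0]
    missing = [c for c in ("log2FoldChange", "pvalue", "padj") if c not in raw.columns]
    if missing:
        raise ValidationError(f"{path}: missing required DE columns {missing}")

    out = pd.DataFrame({"gene_id": raw[gene_col].astype(str)})
    if strip_gene_versions:
        out["gene_id"] = out["gene_id"].map(_strip_version)
    dupes = out["gene_id"][out["gene_id"].duplicated()]
    if not dupes.empty:
        raise ValidationError(f"{path}: duplicate gene id {dupes.iloc[0]!r}")

    for src, dst in _DESEQ2_MAP.items():
        if src in raw.columns:
            out[dst] = _numeric(raw[src], path, src)
        else:
            out[dst] = np.nan
    _validate_de(out, path)
    return out[DE_COLUMNS].reset_index(drop=True)


def _validate_de(de: pd.DataFrame, origin: object) -> None:
    if de["log_fc"].isna().any() or not np.isfinite(de["log_fc"]).all():
        bad = de.loc[~np.isfinite(de["log_fc"].fillna(np.inf)), "gene_id"]
        raise ValidationError(f"{origin}: non-finite log fold change (gene {bad.iloc[0]!r})")
    for col in ("p_value", "adj_p"):
        vals = de[col].dropna()
        if ((vals < 0) | (vals > 1)).any():
            raise ValidationError(f"{origin}: {col} outside [0, 1]")
    if de["p_value"].isna().any():
        raise ValidationError(f"{origin}: missing p_value")
    present = de["base_mean"].dropna()
    if (present < 0).any():
        raise ValidationError(f"{origin}: negative base_mean")


def write_de_table(de: pd.DataFrame, path: str | Path) -> None:
    """Write a DE table in the DESeq2 column dialect; missing cells become NA.

    The written file reads back through :func:`read_de_table` with values
    and missingness preserved exactly.
    """
    out = de[DE_COLUMNS].rename(columns={v: k for k, v in _DESEQ2_MAP.items()})
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_matrix(path: str | Path, kind: str) -> pd.DataFrame:
    """Read a gene x tissue matrix.

    Parameters
    ----------
    path
        Tab-separated file: header row of tissue ids, first column gene ids.
    kind
        ``"expression_tpm"`` (values >= 0 where present) or ``"vg"``
        (values > 0 where present).

    Returns
    -------
    pandas.DataFrame
        Genes on the index, tissues on the columns, NaN marking missing
        cells. ``df.attrs["kind"]`` records the matrix kind.
    """
    if kind not in ("expression_tpm", "vg"):
        raise ValueError(f"unknown matrix kind: {kind!r}")
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, index_col=0)
    raw.index = raw.index.astype(str)
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise ValidationError(f"{path}: duplicate gene id {dup!r}")
    if raw.columns.duplicated().any():
        dup = raw.columns[raw.columns.duplicated()][0]
        raise ValidationError(f"{path}: duplicate tissue id {dup!r}")
    mat = pd.DataFrame(index=raw.index)
    for col in raw.columns:
        mat[col] = _numeric(raw[col], path, col)
    validate_matrix(mat, kind, origin=path)
    mat.attrs["kind"] = kind
    mat.index.name = "gene_id"
    return mat


def validate_matrix(mat: pd.DataFrame, kind: str, origin: object = "matrix") -> None:
    """Enforce kind-specific value invariants, naming the offending cell."""
    values = mat.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        bad = (values < 0) if kind == "expression_tpm" else (values <= 0)
    bad &= ~np.isnan(values)
    if bad.any():
        g, t = np.argwhere(bad)[0]
        constraint = ">= 0" if kind == "expression_tpm" else "> 0"
        raise ValidationError(
            f"{origin}: {kind} value {values[g, t]!r} at gene {mat.index[g]!r}, "
            f"tissue {mat.columns[t]!r} violates {constraint}"
        )


def write_matrix(mat: pd.DataFrame, path: str | Path) -> None:
    """Write a gene x tissue matrix; missing cells become NA."""
    out = mat.copy()
    out.index.name = out.index.name or "gene_id"
    out.to_csv(path, sep="\t", na_rep="NA")


@dataclass
class GeneSetCollection:
    """Named gene sets with optional per-set descriptions (GMT semantics)."""

    sets: dict[str, set[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[str]:
        return iter(self.sets)

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()

    def restricted(self, universe: set[str]) -> "GeneSetCollection":
        """Intersect every set with *universe*, dropping sets that empty out."""
        kept = {
            name: members & universe
            for name, members in self.sets.items()
            if members & universe
        }
        return GeneSetCollection(
            sets=kept,
            descriptions={n: self.descriptions.get(n, "") for n in kept},
        )


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file: name, description, then member gene ids.

    Duplicate genes within a line are deduplicated; an empty file yields an
    empty collection.
    """
    path = Path(path)
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}: line {lineno} has {len(fields)} fields, expected >= 3"
                )
            name, desc = fields[0], fields[1]
            if name in coll.sets:
                raise ValidationError(f"{path}: duplicate set name {name!r} at line {lineno}")
            members = {g for g in fields[2:] if g}
            if not members:
                raise ValidationError(f"{path}: set {name!r} at line {lineno} is empty")
            coll.sets[name] = members
            coll.descriptions[name] = desc
    return coll
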