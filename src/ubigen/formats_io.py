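"""Readers and writers for on-disk artifacts.

Supported formats:

* GCT 1.2 expression matrices (the distribution format of GTEx raw counts):
  two header lines (``#1.2`` and ``<n_genes>\\t<n_samples>``), then a table
  with ``NAME`` and ``Description`` columns followed by one column per sample.
* Plain TSV expression matrices: first column gene IDs, remaining columns
  numeric sample values.
* Gene lists: one identifier per line, ``#`` comments and blank lines allowed.
* Gene-length tables: TSV of gene ID and transcript length in base pairs.
* Drug-statistics tables: per (gene, drug[, concentration]) t-test p-value
  and log fold change, with optional MOA/ATC group labels.
* Score tables written by :func:`write_scores`.

Gene identifiers are treated as opaque strings.  Ensembl-style version
suffixes (``.N``) are stripped on load by default so that matrices from
different sources join on unversioned IDs.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "DuplicateGeneWarning",
    "ExpressionMatrix",
    "GeneList",
    "DrugStatsTable",
    "strip_gene_versions",
    "read_gct",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_gene_list",
    "read_gene_lengths",
    "read_drug_stats",
    "write_scores",
    "read_scores",
]


class FormatError(ValueError):
    """A file does not conform to its declared on-disk format."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


class DuplicateGeneWarning(UserWarning):
    """Duplicate gene IDs were collapsed to their first occurrence."""


_VERSION_RE = re.compile(r"\.\d+$")


def strip_gene_versions(ids: Iterable[str]) -> list[str]:
    """Remove trailing Ensembl-style ``.N`` version suffixes."""
    return [_VERSION_RE.sub("", str(g)) for g in ids]


@dataclass
class ExpressionMatrix:
    """Non-negative gene x sample value table.

    ``data`` is a float DataFrame indexed by gene ID with one column per
    sample.  ``meta`` carries free-text provenance (source name,
    normalization applied, dropped-row counts).
    """

    data: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            raise ValidationError("duplicate gene IDs in expression matrix")
        if df.columns.has_duplicates:
            raise ValidationError("duplicate sample IDs in expression matrix")
        values = df.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValidationError("expression values must be finite")
        if (values < 0).any():
            raise ValidationError("expression values must be non-negative")
        self.data = df.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def require_scoring_shape(self) -> None:
        """Scoring needs at least one gene and two samples."""
        if self.n_genes < 1 or self.n_samples < 2:
            raise ValidationError(
                f"scoring requires >=1 gene and >=2 samples, got "
                f"{self.n_genes} x {self.n_samples}"
            )


@dataclass(frozen=True)
class GeneList:
    """A named set of gene identifiers."""

    name: str
    gene_ids: frozenset[str]

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.gene_ids


_DRUG_COLUMN_ALIASES = {
    "gene_id": ("gene_id", "gene", "ensembl_id"),
    "drug_id": ("drug_id", "drug", "pert_id", "compound"),
    "p_value": ("p_value", "pvalue", "p", "p.value"),
    "log_fc": ("log_fc", "logfc", "lfc", "log2fc"),
    "concentration": ("concentration", "conc", "dose"),
    "moa": ("moa", "mechanism"),
    "atc": ("atc", "atc_code"),
}


@dataclass
class DrugStatsTable:
    """Per (gene, drug[, concentration]) significance and effect-size records.

    Columns: ``gene_id``, ``drug_id``, ``concentration`` (may be missing),
    ``moa``/``atc`` (may be missing), ``p_value`` in [0, 1], ``log_fc``.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records.copy()
        for col in ("gene_id", "drug_id", "p_value", "log_fc"):
            if col not in df.columns:
                raise ValidationError(f"drug-stats table is missing column {col!r}")
        for col in ("concentration", "moa", "atc"):
            if col not in df.columns:
                df[col] = pd.NA
        df["p_value"] = pd.to_numeric(df["p_value"])
        df["log_fc"] = pd.to_numeric(df["log_fc"])
        bad_p = df.index[(df["p_value"] < 0) | (df["p_value"] > 1) | df["p_value"].isna()]
        if len(bad_p):
            raise ValidationError(
                f"p_value outside [0,1] in rows {list(bad_p[:10])}"
                + (" ..." if len(bad_p) > 10 else "")
            )
        if not np.isfinite(df["log_fc"].to_numpy(dtype=float)).all():
            raise ValidationError("log_fc values must be finite")
        key = df[["gene_id", "drug_id", "concentration"]].astype(str)
        dup = key.duplicated()
        if dup.any():
            raise ValidationError(
                f"duplicate (gene, drug, concentration) rows: {list(df.index[dup][:10])}"
            )
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def drugs(self) -> list[str]:
        return sorted(self.records["drug_id"].astype(str).unique())

    @property
    def genes(self) -> set[str]:
        return set(self.records["gene_id"].astype(str))


def _dedupe_first(df: pd.DataFrame, what: str) -> pd.DataFrame:
    """Keep the first row per duplicated index label, warning with the count.

    Deterministic by construction; the number of collapsed rows is reported so
    callers can verify no row vanished silently.
    """
    dup_mask = df.index.duplicated(keep="first")
    n_dup = int(dup_mask.sum())
    if n_dup:
        dup_ids = sorted(set(df.index[dup_mask]))
        warnings.warn(
            f"{what}: {n_dup} duplicate gene ID row(s) collapsed to first "
            f"occurrence ({', '.join(dup_ids[:5])}{'...' if len(dup_ids) > 5 else ''})",
            DuplicateGeneWarning,
            stacklevel=3,
        )
        df = df[~dup_mask]
    return df


def read_gct(path: str | Path, strip_versions: bool = True) -> ExpressionMatrix:
    """Read a GCT 1.2 expression matrix.

    The ``Description`` column is discarded into ``meta['descriptions']``.
    Duplicate gene IDs keep their first occurrence with a warning.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        version = fh.readline().rstrip("\n")
        if version.strip() != "#1.2":
            raise FormatError(f"{path}: expected GCT version line '#1.2', found {version!r}")
        dims_line = fh.readline().rstrip("\n")
        parts = dims_line.split("\t")
        try:
            n_genes, n_samples = int(parts[0]), int(parts[1])
        except (ValueError, IndexError):
            raise FormatError(
                f"{path}: malformed GCT dimensions line {dims_line!r}"
            ) from None
        table = pd.read_csv(fh, sep="\t", keep_default_na=False, dtype=str)
    if table.shape[1] < 2:
        raise FormatError(f"{path}: GCT table must have NAME and Description columns")
    found_genes = table.shape[0]
    found_samples = table.shape[1] - 2
    if found_genes != n_genes or found_samples != n_samples:
        raise FormatError(
            f"{path}: GCT declares {n_genes} genes x {n_samples} samples but "
            f"contains {found_genes} x {found_samples}"
        )
    gene_ids = table.iloc[:, 0].astype(str)
    if strip_versions:
        gene_ids = pd.Index(strip_gene_versions(gene_ids))
    descriptions = dict(zip(gene_ids, table.iloc[:, 1]))
    numeric = _to_numeric_block(table.iloc[:, 2:], path)
    numeric.index = pd.Index(gene_ids, name="gene_id")
    numeric = _dedupe_first(numeric, str(path))
    return ExpressionMatrix(
        numeric,
        meta={"source": str(path), "format": "gct-1.2", "descriptions": descriptions},
    )


def _to_numeric_block(block: pd.DataFrame, path: Path) -> pd.DataFrame:
    out = {}
    for col in block.columns:
        converted = pd.to_numeric(block[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(
                f"{path}: non-numeric value {block[col].iloc[row]!r} at data row "
                f"{row + 1}, column {col!r}"
            )
        out[col] = converted
    return pd.DataFrame(out, index=block.index)


_SCORE_COLUMNS = ("s_b", "s_l_raw", "s_v_raw", "s_l", "s_v", "score", "rank", "percentile")


def read_expression_tsv(path: str | Path, strip_versions: bool = True) -> ExpressionMatrix:
    """Read a plain TSV expression matrix (gene ID column + sample columns)."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    if first.startswith("#"):
        if "score table" in first:
            raise FormatError(
                f"{path}: file has a score-table schema; use read_scores() instead"
            )
        raise FormatError(f"{path}: unexpected comment header {first.strip()!r}")
    table = pd.read_csv(path, sep="\t", keep_default_na=False, dtype=str)
    if table.shape[1] < 2:
        raise FormatError(f"{path}: expected a gene ID column plus >=1 sample column")
    lowered = {c.lower() for c in table.columns}
    if {"score", "rank", "percentile"} <= lowered:
        raise FormatError(
            f"{path}: file has a score-table schema; use read_scores() instead"
        )
    gene_ids = table.iloc[:, 0].astype(str)
    if strip_versions:
        gene_ids = pd.Index(strip_gene_versions(gene_ids))
    numeric = _to_numeric_block(table.iloc[:, 1:], path)
    numeric.index = pd.Index(gene_ids, name="gene_id")
    numeric = _dedupe_first(numeric, str(path))
    return ExpressionMatrix(numeric, meta={"source": str(path), "format": "tsv"})


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.data.rename_axis("gene_id").to_csv(path, sep="\t")


def read_gene_list(path: str | Path, name: str | None = None,
                   strip_versions: bool = True) -> GeneList:
    """Read a one-ID-per-line gene list (``#`` comments allowed)."""
    path = Path(path)
    ids: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            ids.append(line)
    if strip_versions:
        ids = strip_gene_versions(ids)
    return GeneList(name=name or path.stem, gene_ids=frozenset(ids))


def read_gene_lengths(path: str | Path, strip_versions: bool = True) -> pd.Series:
    """Read a gene-length TSV (gene ID, length in bp) into a Series."""
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype={0: str})
    if table.shape[1] < 2:
        raise FormatError(f"{path}: expected gene ID and length columns")
    ids = table.iloc[:, 0].astype(str)
    if strip_versions:
        ids = strip_gene_versions(ids)
    lengths = pd.to_numeric(table.iloc[:, 1], errors="coerce")
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValidationError(f"{path}: gene lengths must be positive numbers")
    out = pd.Series(lengths.to_numpy(dtype=float), index=pd.Index(ids, name="gene_id"),
                    name="length_bp")
    return out[~out.index.duplicated(keep="first")]


def read_drug_stats(path: str | Path, strip_versions: bool = True) -> DrugStatsTable:
    """Read a drug-statistics TSV.

    Column names are matched case-insensitively against common aliases
    (``gene``/``gene_id``, ``drug``/``pert_id``, ``p``/``p_value``,
    ``lfc``/``log_fc``, optional ``concentration``/``moa``/``atc``).
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t")
    colmap: dict[str, str] = {}
    lowered = {c.lower(): c for c in table.columns}
    for canonical, aliases in _DRUG_COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in lowered:
                colmap[canonical] = lowered[alias]
                break
    missing = [c for c in ("gene_id", "drug_id", "p_value", "log_fc") if c not in colmap]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    df = pd.DataFrame({canon: table[orig] for canon, orig in colmap.items()})
    df["gene_id"] = df["gene_id"].astype(str)
    if strip_versions:
        df["gene_id"] = strip_gene_versions(df["gene_id"])
    df["drug_id"] = df["drug_id"].astype(str)
    return DrugStatsTable(df)


def write_scores(score_table, path: str | Path) -> None:
    """Write a score table as commented TSV (lossless round-trip)."""
    from ubigen.scoring_core import ScoreTable  # local import avoids a cycle

    assert isinstance(score_table, ScoreTable)
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# ubigen score table\n")
        fh.write(
            "# columns: gene_id, s_b (breadth subscore), s_l_raw/s_v_raw (raw "
            "level/variation), s_l/s_v (min-max normalized), score (composite), "
            "rank (1 = highest), percentile (0-100)\n"
        )
        score_table.data.rename_axis("gene_id").to_csv(fh, sep="\t", lineterminator="\n")


def read_scores(path: str | Path):
    """Read a score table written by :func:`write_scores`."""
    from ubigen.scoring_core import ScoreTable

    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", index_col="gene_id")
    missing = [c for c in _SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: score table is missing column(s) {missing}")
    df.index = df.index.astype(str)
    if len(df):
        pct = df["percentile"].to_numpy(dtype=float)
        if (pct < 0).any() or (pct > 100).any():
            raise ValidationError(f"{path}: percentile values outside [0, 100]")
    return ScoreTable(df[list(_SCORE_COLUMNS)])
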