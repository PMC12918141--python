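"""Ubiquity cutoff, cross-dataset sector classification and gene reports.

A gene is called *ubiquitous* in a dataset when it belongs to the top 5% of
that dataset's ranking.  The cutoff is count-based: exactly
``floor(top_fraction * N)`` genes qualify, taken in deterministic rank order.

Comparing two datasets assigns every shared gene a two-bit *sector* label:
the first bit is membership in dataset A's ubiquitous set, the second in
dataset B's.  Sector "11" genes are ubiquitous in both (robust reference
candidates), "10" only in A, "01" only in B, "00" in neither.  Each
dataset's cutoff is computed on its full gene list before restricting to
the shared genes, so a dataset's ubiquitous count is a property of that
dataset alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from ubigen.formats_io import GeneList, ValidationError
from ubigen.scoring_core import ScoreTable

__all__ = [
    "SECTORS",
    "SectorAssignment",
    "ubiquitous_set",
    "classify_sectors",
    "spearman_rho",
    "list_sector_profile",
    "gene_report",
    "multi_list_intersections",
]

SECTORS = ("00", "01", "10", "11")


@dataclass
class SectorAssignment:
    """Per shared gene: sector label plus both datasets' scores/percentiles."""

    data: pd.DataFrame  # index gene_id; sector, score_a, score_b, percentile_a, percentile_b
    top_fraction: float

    @property
    def sectors(self) -> pd.Series:
        return self.data["sector"]

    @property
    def shared_genes(self) -> set[str]:
        return set(self.data.index)

    def counts(self) -> dict[str, int]:
        vc = self.data["sector"].value_counts()
        return {s: int(vc.get(s, 0)) for s in SECTORS}

    def genes_in(self, sector: str) -> set[str]:
        return set(self.data.index[self.data["sector"] == sector])


def ubiquitous_set(scores: ScoreTable, top_fraction: float = 0.05) -> set[str]:
    """The top ``floor(top_fraction * N)`` genes of a ranking.

    Count-based by design: with N = 55,242 genes exactly 2,762 genes are
    ubiquitous at the default 5% cutoff, with N = 12,382 exactly 619.
    """
    if not (0 < top_fraction <= 1):
        raise ValidationError(f"top_fraction must be in (0, 1], got {top_fraction}")
    if len(scores) < 1:
        raise ValidationError("cannot take the top fraction of an empty ranking")
    k = math.floor(top_fraction * len(scores))
    return set(scores.top(k))


def classify_sectors(
    a: ScoreTable, b: ScoreTable, top_fraction: float = 0.05
) -> SectorAssignment:
    """Assign each gene shared by two rankings a 00/01/10/11 sector label."""
    shared = sorted(set(a.gene_ids) & set(b.gene_ids))
    if not shared:
        raise ValidationError("the two score tables share no genes")
    ubiq_a = ubiquitous_set(a, top_fraction)
    ubiq_b = ubiquitous_set(b, top_fraction)
    bit_a = np.array([g in ubiq_a for g in shared])
    bit_b = np.array([g in ubiq_b for g in shared])
    sector = np.where(bit_a, "1", "0").astype(object) + np.where(bit_b, "1", "0")
    df = pd.DataFrame(
        {
            "sector": sector,
            "score_a": a.scores.reindex(shared).to_numpy(),
            "score_b": b.scores.reindex(shared).to_numpy(),
            "percentile_a": a.percentiles.reindex(shared).to_numpy(),
            "percentile_b": b.percentiles.reindex(shared).to_numpy(),
        },
        index=pd.Index(shared, name="gene_id"),
    )
    return SectorAssignment(df, top_fraction)


def spearman_rho(a: ScoreTable, b: ScoreTable) -> float:
    """Spearman rank correlation of two score tables over their shared genes."""
    shared = sorted(set(a.gene_ids) & set(b.gene_ids))
    if len(shared) < 3:
        raise ValidationError(f"need >=3 shared genes for Spearman, got {len(shared)}")
    rho, _ = spearmanr(
        a.scores.reindex(shared).to_numpy(), b.scores.reindex(shared).to_numpy()
    )
    return float(rho)


def list_sector_profile(
    gene_list: GeneList, sectors: SectorAssignment
) -> pd.DataFrame:
    """How a gene list distributes over the four sectors.

    For every sector: the number of list genes in it, the fraction of
    covered list genes it holds, and the over-representation ratio relative
    to the sector's share of all shared genes.  Genes of the list absent
    from the shared-gene universe are reported via the ``uncovered``
    attribute of the returned frame (``df.attrs['uncovered']``).
    """
    shared = sectors.shared_genes
    covered = gene_list.gene_ids & shared
    if not covered:
        raise ValidationError(f"gene list {gene_list.name!r} has no gene in the shared set")
    total_counts = sectors.counts()
    n_shared = len(shared)
    rows = []
    sub = sectors.sectors.loc[sorted(covered)]
    for sector in SECTORS:
        n_list = int((sub == sector).sum())
        frac_list = n_list / len(covered)
        frac_all = total_counts[sector] / n_shared
        ratio = frac_list / frac_all if frac_all > 0 else np.nan
        rows.append(
            {
                "sector": sector,
                "n_list": n_list,
                "fraction_of_list": frac_list,
                "fraction_of_all": frac_all,
                "overrepresentation": ratio,
            }
        )
    df = pd.DataFrame(rows).set_index("sector")
    df.attrs["uncovered"] = len(gene_list.gene_ids) - len(covered)
    df.attrs["list_name"] = gene_list.name
    return df


def gene_report(
    gene_ids: Sequence[str],
    tables: Mapping[str, ScoreTable],
    sectors: SectorAssignment | None = None,
) -> pd.DataFrame:
    """Per-gene, per-dataset score/rank/percentile report.

    Genes absent from a dataset appear with ``present = False`` and missing
    values rather than zeros.  When a sector assignment is supplied the
    gene's sector label (or missing) is included.
    """
    rows = []
    for gene in gene_ids:
        for name, table in tables.items():
            present = gene in table.data.index
            row = {
                "gene_id": gene,
                "dataset": name,
                "present": present,
                "score": float(table.data.at[gene, "score"]) if present else np.nan,
                "rank": int(table.data.at[gene, "rank"]) if present else pd.NA,
                "percentile": float(table.data.at[gene, "percentile"]) if present else np.nan,
            }
            if sectors is not None:
                row["sector"] = (
                    sectors.sectors.get(gene, pd.NA) if gene in sectors.shared_genes else pd.NA
                )
            rows.append(row)
    return pd.DataFrame(rows)


def multi_list_intersections(lists: Sequence[GeneList]) -> dict[str, int]:
    """Counts of every non-empty membership pattern across gene lists.

    Pattern ``"101"`` counts genes in the first and third list but not the
    second; counts sum to the size of the union.
    """
    if len(lists) < 2:
        raise ValidationError("need at least 2 gene lists")
    union = set().union(*(gl.gene_ids for gl in lists))
    counts: dict[str, int] = {}
    membership = {g: "".join("1" if g in gl else "0" for gl in lists) for g in union}
    for pattern in membership.values():
        counts[pattern] = counts.get(pattern, 0) + 1
    return counts
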