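"""Over-representation analysis along a ranking.

The *sliding-bucket* analysis splits a ranked gene list into consecutive
buckets (2.5% of genes each by default; the last bucket may be smaller) and
runs an independent over-representation analysis per bucket: for every term
of an annotation collection the one-sided hypergeometric tail probability
of the observed bucket/term overlap is computed against a custom background
(the intersection of ranked and annotated genes), p-values are adjusted
with Benjamini-Hochberg FDR across all terms of the run, and the number of
significant terms per annotation source is counted.  A ranking whose top
captures biologically central genes shows counts that fall off from the top
bucket downwards.

The same machinery serves single-set enrichment of an arbitrary query
(e.g. the sector-11 genes of a two-dataset comparison).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from scipy.stats import false_discovery_control

from ubigen.formats_io import ValidationError
from ubigen.scoring_core import ScoreTable

__all__ = [
    "GeneSetCollection",
    "BucketPartition",
    "read_collection",
    "bucketize",
    "hypergeom_test",
    "enrich_set",
    "sliding_enrichment",
]

HIGHLY_SIGNIFICANT_NEGLOG10 = 16.0  # "highly significant" band: -log10(p_adj) >= 16


@dataclass(frozen=True)
class GeneSetCollection:
    """Annotation terms: term_id -> (source label, member gene set)."""

    terms: dict[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for term_id, (_, members) in self.terms.items():
            if not members:
                raise ValidationError(f"term {term_id!r} has an empty member set")

    def __len__(self) -> int:
        return len(self.terms)

    @property
    def sources(self) -> list[str]:
        return sorted({src for src, _ in self.terms.values()})

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for _, members in self.terms.values():
            out |= members
        return out


@dataclass
class BucketPartition:
    """Consecutive rank-order slices of a ranking."""

    buckets: list[list[str]]
    bucket_size: int
    fraction: float

    def __len__(self) -> int:
        return len(self.buckets)


def read_collection(path: str | Path) -> GeneSetCollection:
    """Read a GMT-style TSV: term_id <tab> source <tab> gene1 <tab> gene2 ..."""
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"{path}:{lineno}: expected term, source, >=1 gene")
            term_id, source, genes = parts[0], parts[1], parts[2:]
            if term_id in terms:
                raise ValidationError(f"{path}:{lineno}: duplicate term ID {term_id!r}")
            terms[term_id] = (source, frozenset(g for g in genes if g))
    return GeneSetCollection(terms)


def bucketize(ranking: ScoreTable, fraction: float = 0.025) -> BucketPartition:
    """Partition a ranking into buckets of ``ceil(fraction * N)`` genes.

    All buckets except possibly the last have exactly the bucket size; the
    last one (lowest-ranking genes) may be smaller.
    """
    if not (0 < fraction <= 1):
        raise ValidationError(f"fraction must be in (0, 1], got {fraction}")
    genes = ranking.gene_ids  # already in rank order
    n = len(genes)
    if n == 0:
        raise ValidationError("cannot bucketize an empty ranking")
    b = math.ceil(fraction * n)
    buckets = [genes[i : i + b] for i in range(0, n, b)]
    return BucketPartition(buckets, b, fraction)


def hypergeom_test(query: set[str], term: set[str], background: set[str]) -> float:
    """One-sided over-representation p-value P[X >= k].

    X follows the hypergeometric distribution for drawing ``|query|`` genes
    from ``|background|`` of which ``|term & background|`` are annotated;
    k is the observed overlap.  The term is intersected with the background
    before testing; the query must be a subset of the background.
    """
    if not background:
        raise ValidationError("background is empty")
    if not query <= background:
        raise ValidationError("query must be a subset of the background")
    term_bg = term & background
    k = len(query & term_bg)
    if len(term_bg) == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, len(background), len(term_bg), len(query)))


def enrich_set(
    query: set[str],
    collection: GeneSetCollection,
    background: set[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Over-representation of every collection term in one query set.

    Query genes outside the background are dropped with a warning; terms
    disjoint from the background are skipped (listed in
    ``df.attrs['skipped_terms']``).  Benjamini-Hochberg adjustment is
    applied jointly across all tested terms.  The result frame has one row
    per tested term (term_id, source, term size in background, overlap,
    p, p_adj, significant) and summary counts in ``df.attrs``:
    ``significant_by_source`` and ``highly_significant_by_source``
    (-log10(p_adj) >= 16).
    """
    outside = query - background
    if outside:
        warnings.warn(
            f"{len(outside)} query gene(s) outside the background were dropped",
            stacklevel=2,
        )
        query = query & background
    rows = []
    skipped = []
    for term_id, (source, members) in collection.terms.items():
        term_bg = set(members) & background
        if not term_bg:
            skipped.append(term_id)
            continue
        k = len(query & term_bg)
        p = float(hypergeom.sf(k - 1, len(background), len(term_bg), len(query)))
        rows.append((term_id, source, len(term_bg), k, p))
    df = pd.DataFrame(rows, columns=["term_id", "source", "term_size", "overlap", "p"])
    if len(df):
        df["p_adj"] = false_discovery_control(df["p"].to_numpy(), method="bh")
        df["significant"] = df["p_adj"] <= alpha
    else:
        df["p_adj"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
    sig = df[df["significant"]]
    with np.errstate(divide="ignore"):
        neglog = -np.log10(df["p_adj"].to_numpy(dtype=float)) if len(df) else np.array([])
    high = df[neglog >= HIGHLY_SIGNIFICANT_NEGLOG10] if len(df) else df
    df.attrs["skipped_terms"] = skipped
    df.attrs["significant_by_source"] = sig.groupby("source").size().to_dict()
    df.attrs["highly_significant_by_source"] = high.groupby("source").size().to_dict()
    return df


def sliding_enrichment(
    ranking: ScoreTable,
    collection: GeneSetCollection,
    fraction: float = 0.025,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-bucket, per-source significant-term counts along a ranking.

    The background is the intersection of ranked genes with all annotated
    genes; every bucket is tested independently.  Returns a bucket x source
    count matrix (bucket 0 = top of the ranking).
    """
    partition = bucketize(ranking, fraction)
    background = set(ranking.gene_ids) & collection.all_genes()
    sources = collection.sources
    counts = np.zeros((len(partition), len(sources)), dtype=int)
    for i, bucket in enumerate(partition.buckets):
        query = set(bucket) & background
        if not query:
            continue
        result = enrich_set(query, collection, background, alpha=alpha)
        by_source = result.attrs["significant_by_source"]
        for j, src in enumerate(sources):
            counts[i, j] = by_source.get(src, 0)
    return pd.DataFrame(
        counts, index=pd.RangeIndex(len(partition), name="bucket"), columns=sources
    )
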