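"""Drug influence on ubiquitous versus non-ubiquitous genes.

Starting from per-(gene, drug, concentration) t-test summaries, a drug is
said to *affect* a gene when any of its records for that gene is significant
(p <= 0.05 by default).  For each drug the affected fractions of the
ubiquitous and the non-ubiquitous gene sets are compared; their ratio
(non-ubiquitous over ubiquitous) quantifies the drug's bias: ratios below 1
mean the drug disproportionately hits ubiquitous genes.

Additional summaries: the |logFC|-weighted mean ubiquity score of a drug's
affected genes, per-group (MOA/ATC) aggregates, and mean |logFC| per
cross-dataset sector.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from ubigen.formats_io import DrugStatsTable, ValidationError
from ubigen.ranking_classification import SectorAssignment
from ubigen.scoring_core import ScoreTable

__all__ = [
    "DrugEffectSummary",
    "significant_pairs",
    "affected_genes_by_drug",
    "affected_proportions",
    "rank_by_bias",
    "group_summaries",
    "weighted_mean_score",
    "sector_effect_sizes",
]


@dataclass
class DrugEffectSummary:
    """Affected-gene statistics for one drug (or one drug group)."""

    drug_id: str
    n_affected_ubiq: int
    n_affected_nonubiq: int
    prop_ubiq: float
    prop_nonubiq: float
    bias_ratio: float | None  # None when both proportions are 0; inf allowed
    mean_abs_lfc: float
    n_ubiq_total: int = 0
    n_nonubiq_total: int = 0
    weighted_mean_score: float | None = None
    n_drugs: int = 1  # >1 for group summaries


def significant_pairs(table: DrugStatsTable, alpha: float = 0.05) -> DrugStatsTable:
    """Records whose p-value is at or below alpha (boundary inclusive)."""
    if not (0 < alpha < 1):
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    kept = table.records[table.records["p_value"] <= alpha]
    return DrugStatsTable(kept.reset_index(drop=True))


def affected_genes_by_drug(pairs: DrugStatsTable) -> dict[str, set[str]]:
    """Gene sets affected per drug; any significant concentration counts."""
    out: dict[str, set[str]] = {}
    for drug, sub in pairs.records.groupby("drug_id", sort=True):
        out[str(drug)] = set(sub["gene_id"].astype(str))
    return out


def _bias_ratio(prop_ubiq: float, prop_nonubiq: float) -> float | None:
    if prop_ubiq == 0:
        return math.inf if prop_nonubiq > 0 else None
    return prop_nonubiq / prop_ubiq


def affected_proportions(
    pairs: DrugStatsTable,
    ubiq: set[str],
    universe: set[str],
) -> dict[str, DrugEffectSummary]:
    """Per-drug affected fractions of ubiquitous and non-ubiquitous genes.

    ``pairs`` should already be filtered to significant records.  The
    universe is the set of genes present in both the scoring dataset and
    the drug dataset; affected genes outside it are ignored.
    """
    if not ubiq <= universe:
        raise ValidationError("ubiquitous set must be a subset of the universe")
    nonubiq = universe - ubiq
    if not ubiq or not nonubiq:
        raise ValidationError("both the ubiquitous set and its complement must be non-empty")
    rec = pairs.records
    in_universe = rec["gene_id"].isin(universe)
    rec = rec[in_universe]
    summaries: dict[str, DrugEffectSummary] = {}
    for drug in pairs.drugs:
        sub = rec[rec["drug_id"] == drug]
        affected = set(sub["gene_id"].astype(str))
        n_u = len(affected & ubiq)
        n_n = len(affected & nonubiq)
        prop_u = n_u / len(ubiq)
        prop_n = n_n / len(nonubiq)
        mean_abs = float(sub["log_fc"].abs().mean()) if len(sub) else 0.0
        summaries[drug] = DrugEffectSummary(
            drug_id=drug,
            n_affected_ubiq=n_u,
            n_affected_nonubiq=n_n,
            prop_ubiq=prop_u,
            prop_nonubiq=prop_n,
            bias_ratio=_bias_ratio(prop_u, prop_n),
            mean_abs_lfc=mean_abs,
            n_ubiq_total=len(ubiq),
            n_nonubiq_total=len(nonubiq),
        )
    return summaries


def rank_by_bias(
    summaries: Mapping[str, DrugEffectSummary], top_n: int = 10
) -> tuple[list[str], list[str]]:
    """(most ubiquitous-biased, most non-ubiquitous-biased) drug lists.

    Smallest bias ratios first in the first list, largest (infinity sorts
    above any finite ratio) first in the second; drugs without a defined
    ratio are excluded; ties broken by drug ID.
    """
    defined = [(s.bias_ratio, d) for d, s in summaries.items() if s.bias_ratio is not None]
    asc = sorted(defined, key=lambda t: (t[0], t[1]))
    desc = sorted(defined, key=lambda t: (-t[0], t[1]))
    return [d for _, d in asc[:top_n]], [d for _, d in desc[:top_n]]


def group_summaries(
    summaries: Mapping[str, DrugEffectSummary],
    grouping: Mapping[str, str],
    pooled: bool = False,
) -> tuple[dict[str, DrugEffectSummary], int]:
    """Aggregate per-drug summaries into labelled groups (MOA or ATC class).

    Default aggregation is the unweighted mean of member drugs' proportions
    and mean |logFC|; ``pooled = True`` instead sums the affected counts
    (a gene affected by several member drugs is counted once per drug) and
    divides by ``n_drugs * denominator``.  Returns the group summaries and
    the number of unlabeled drugs skipped.
    """
    if not grouping:
        raise ValidationError("grouping map is empty")
    groups: dict[str, list[DrugEffectSummary]] = {}
    n_skipped = 0
    for drug, summary in summaries.items():
        label = grouping.get(drug)
        if label is None or (isinstance(label, float) and math.isnan(label)):
            n_skipped += 1
            continue
        groups.setdefault(str(label), []).append(summary)
    out: dict[str, DrugEffectSummary] = {}
    for label, members in sorted(groups.items()):
        n = len(members)
        if pooled:
            denom_u = sum(m.n_ubiq_total for m in members)
            denom_n = sum(m.n_nonubiq_total for m in members)
            if denom_u == 0 or denom_n == 0:
                raise ValidationError("pooled grouping needs per-drug denominators")
            prop_u = sum(m.n_affected_ubiq for m in members) / denom_u
            prop_n = sum(m.n_affected_nonubiq for m in members) / denom_n
        else:
            prop_u = float(np.mean([m.prop_ubiq for m in members]))
            prop_n = float(np.mean([m.prop_nonubiq for m in members]))
        out[label] = DrugEffectSummary(
            drug_id=label,
            n_affected_ubiq=sum(m.n_affected_ubiq for m in members),
            n_affected_nonubiq=sum(m.n_affected_nonubiq for m in members),
            prop_ubiq=prop_u,
            prop_nonubiq=prop_n,
            bias_ratio=_bias_ratio(prop_u, prop_n),
            mean_abs_lfc=float(np.mean([m.mean_abs_lfc for m in members])),
            n_ubiq_total=sum(m.n_ubiq_total for m in members),
            n_nonubiq_total=sum(m.n_nonubiq_total for m in members),
            n_drugs=n,
        )
    return out, n_skipped


def weighted_mean_score(
    pairs: DrugStatsTable,
    scores: ScoreTable,
    drug_id: str | None = None,
    lfc_collapse: str = "max",
) -> float:
    """|logFC|-weighted mean ubiquity score of a drug's affected genes.

    Per gene the |logFC| across the drug's significant records is collapsed
    with ``max`` (strongest observed effect; ``mean`` available).  Genes
    without a score are ignored; if every weight is zero an unweighted mean
    is returned with a warning.
    """
    rec = pairs.records
    if drug_id is not None:
        rec = rec[rec["drug_id"] == drug_id]
    if lfc_collapse not in ("max", "mean"):
        raise ValidationError(f"unknown lfc_collapse {lfc_collapse!r}")
    per_gene = rec.assign(abs_lfc=rec["log_fc"].abs()).groupby("gene_id")["abs_lfc"]
    weights = per_gene.max() if lfc_collapse == "max" else per_gene.mean()
    scored = weights.index.intersection(scores.data.index)
    if len(scored) == 0:
        raise ValidationError("no affected gene has a score")
    w = weights.loc[scored].to_numpy(dtype=float)
    s = scores.scores.loc[scored].to_numpy(dtype=float)
    if w.sum() == 0:
        warnings.warn("all |logFC| weights are zero; returning unweighted mean", stacklevel=2)
        return float(s.mean())
    return float(np.average(s, weights=w))


def sector_effect_sizes(
    pairs: DrugStatsTable,
    sectors: SectorAssignment,
    grouping: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Mean |logFC| of significant records grouped by gene sector (x drug label).

    Sectors (or sector-label combinations) without any record are simply
    absent from the result rather than reported as zero.
    """
    rec = pairs.records.copy()
    rec["sector"] = rec["gene_id"].map(sectors.sectors)
    rec = rec[rec["sector"].notna()]
    rec["abs_lfc"] = rec["log_fc"].abs()
    if grouping is None:
        grouped = rec.groupby("sector")["abs_lfc"].agg(["mean", "count"])
    else:
        rec["group"] = rec["drug_id"].map(dict(grouping))
        rec = rec[rec["group"].notna()]
        grouped = rec.groupby(["sector", "group"])["abs_lfc"].agg(["mean", "count"])
    return grouped.rename(columns={"mean": "mean_abs_lfc", "count": "n_records"})
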