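"""Composite ubiquity ("Ubigen") scoring.

A gene's score combines three criterion classes:

* **breadth** — the fraction of samples in which the gene meets or exceeds a
  per-sample expression threshold (95th percentile by default, computed over
  all values of the sample including zeros);
* **level** — the median (or mean) expression over the gene's strictly
  positive values;
* **variation** — a dispersion statistic over the positive values, by
  default the quartile-based coefficient of variation
  QCV = (Q3 - Q1) / median, a robust scale-free spread measure.

Level and variation are min-max normalized to [0, 1] across genes; breadth
is already a fraction and is used as-is.  The weighted sum of the three
subscores (default weights +0.50 breadth, +0.25 level, -0.25 variation) is
min-max normalized again, so the final score always spans [0, 1] regardless
of the weight configuration.  Because of that final normalization the score
is invariant under positive rescaling of the weight vector; only the weight
ratios matter.

Zero values are excluded from the level and variation statistics: a zero
measurement means "not detected" rather than "expressed at level zero", and
keeping zeros would conflate detection breadth with expression spread.
All quantiles use linear interpolation between order statistics (numpy's
default, R type 7).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ubigen.formats_io import ExpressionMatrix, ValidationError

__all__ = [
    "BREADTH_CRITERIA",
    "LEVEL_CRITERIA",
    "VARIATION_CRITERIA",
    "DEFAULT_WEIGHTS",
    "ScoringConfig",
    "ScoreTable",
    "sample_thresholds",
    "breadth_subscore",
    "level_subscore",
    "variation_subscore",
    "minmax",
    "compute_subscores",
    "compose_from_subscores",
    "compose_scores",
]

BREADTH_CRITERIA = ("above_p95", "above_median", "above_zero")
LEVEL_CRITERIA = ("median", "mean")
VARIATION_CRITERIA = ("qcv", "iqr", "cv", "sd")
DEFAULT_WEIGHTS = (0.5, 0.25, -0.25)

# Instrumentation: incremented once per full subscore computation so callers
# (e.g. the sensitivity grid) can verify subscores are not recomputed per
# weight triple.
SUBSCORE_CALLS = [0]


@dataclass(frozen=True)
class ScoringConfig:
    """One scoring variant: a criterion per class plus signed weights.

    The defaults define the Ubigen score proper.  Weight signs are
    constrained: breadth and level reward (>= 0), variation penalizes
    (<= 0).
    """

    breadth_criterion: str = "above_p95"
    level_criterion: str = "median"
    variation_criterion: str = "qcv"
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS

    def __post_init__(self) -> None:
        if self.breadth_criterion not in BREADTH_CRITERIA:
            raise ValidationError(f"unknown breadth criterion {self.breadth_criterion!r}")
        if self.level_criterion not in LEVEL_CRITERIA:
            raise ValidationError(f"unknown level criterion {self.level_criterion!r}")
        if self.variation_criterion not in VARIATION_CRITERIA:
            raise ValidationError(f"unknown variation criterion {self.variation_criterion!r}")
        w_b, w_l, w_v = self.weights
        if w_b < 0 or w_l < 0 or w_v > 0:
            raise ValidationError(
                "weights must satisfy w_b >= 0, w_l >= 0, w_v <= 0"
            )
        if w_b == 0 and w_l == 0 and w_v == 0:
            raise ValidationError("at least one weight must be non-zero")


class ScoreTable:
    """Per-gene subscores, composite score, rank and percentile.

    Wraps a DataFrame indexed by gene ID with columns ``s_b``, ``s_l_raw``,
    ``s_v_raw``, ``s_l``, ``s_v``, ``score``, ``rank``, ``percentile``,
    stored in rank order (rank 1 first).  Ranks are a permutation of 1..N
    with ties broken by ascending gene ID, so top-k sets are deterministic.
    """

    COLUMNS = ("s_b", "s_l_raw", "s_v_raw", "s_l", "s_v", "score", "rank", "percentile")

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in data.columns]
        if missing:
            raise ValidationError(f"score table missing column(s) {missing}")
        df = data[list(self.COLUMNS)].copy()
        if len(df):
            df["rank"] = df["rank"].astype(int)
            ranks = np.sort(df["rank"].to_numpy())
            if not np.array_equal(ranks, np.arange(1, len(df) + 1)):
                raise ValidationError("ranks must be a permutation of 1..N")
            df = df.sort_values("rank")
        self.data = df

    def __len__(self) -> int:
        return len(self.data)

    def __eq__(self, other) -> bool:
        return isinstance(other, ScoreTable) and self.data.equals(other.data)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def scores(self) -> pd.Series:
        return self.data["score"]

    @property
    def ranks(self) -> pd.Series:
        return self.data["rank"]

    @property
    def percentiles(self) -> pd.Series:
        return self.data["percentile"]

    def top(self, k: int) -> list[str]:
        """The k best-ranked gene IDs (deterministic tie-break)."""
        return list(self.data.index[:k])


def sample_thresholds(matrix: ExpressionMatrix, criterion: str) -> pd.Series:
    """Per-sample expression threshold for a breadth criterion.

    Thresholds are properties of the sample and include zeros, keeping the
    criterion independent of a sample's overall expression scale.
    """
    if criterion not in BREADTH_CRITERIA:
        raise ValidationError(f"unknown breadth criterion {criterion!r}")
    values = matrix.values
    if criterion == "above_p95":
        thr = np.quantile(values, 0.95, axis=0)
    elif criterion == "above_median":
        thr = np.quantile(values, 0.5, axis=0)
    else:  # above_zero
        thr = np.zeros(matrix.n_samples)
    return pd.Series(thr, index=matrix.sample_ids, name="threshold")


def breadth_subscore(matrix: ExpressionMatrix, criterion: str = "above_p95") -> pd.Series:
    """Fraction of samples in which each gene meets its sample's threshold.

    "Meets or exceeds" (>=) for the percentile/median thresholds; strictly
    positive (>) for ``above_zero``, since a zero value is not expressed.
    The denominator is always the full sample count.
    """
    thr = sample_thresholds(matrix, criterion).to_numpy()
    values = matrix.values
    if criterion == "above_zero":
        hits = values > 0
    else:
        hits = values >= thr[np.newaxis, :]
    frac = hits.mean(axis=1)
    return pd.Series(frac, index=matrix.gene_ids, name="s_b")


def _positive_masked(matrix: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray]:
    values = matrix.values
    masked = np.where(values > 0, values, np.nan)
    n_pos = (values > 0).sum(axis=1)
    return masked, n_pos


def level_subscore(matrix: ExpressionMatrix, criterion: str = "median") -> pd.Series:
    """Raw expression level per gene over its strictly positive values.

    A gene with no positive value gets level 0.
    """
    if criterion not in LEVEL_CRITERIA:
        raise ValidationError(f"unknown level criterion {criterion!r}")
    masked, n_pos = _positive_masked(matrix)
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if criterion == "median":
            raw = np.nanmedian(masked, axis=1)
        else:
            raw = np.nanmean(masked, axis=1)
    raw = np.where(n_pos == 0, 0.0, raw)
    return pd.Series(raw, index=matrix.gene_ids, name="s_l_raw")


def variation_subscore(matrix: ExpressionMatrix, criterion: str = "qcv") -> pd.Series:
    """Raw expression-variation statistic per gene over its positive values.

    Conventions for degenerate genes: exactly one positive value gives
    variation 0 (no spread observable); no positive value at all gets the
    dataset's maximum raw variation, so undetected genes cannot outrank
    expressed genes through an undefined-as-zero spread.
    """
    if criterion not in VARIATION_CRITERIA:
        raise ValidationError(f"unknown variation criterion {criterion!r}")
    masked, n_pos = _positive_masked(matrix)
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if criterion in ("qcv", "iqr"):
            q1, q2, q3 = np.nanquantile(masked, [0.25, 0.5, 0.75], axis=1)
            iqr = q3 - q1
            raw = iqr / q2 if criterion == "qcv" else iqr
        elif criterion == "sd":
            raw = np.nanstd(masked, axis=1, ddof=1)
        else:  # cv
            sd = np.nanstd(masked, axis=1, ddof=1)
            raw = sd / np.nanmean(masked, axis=1)
    raw = np.where(n_pos == 1, 0.0, raw)
    detected = n_pos >= 1
    if detected.any():
        worst = float(np.nanmax(np.where(detected, raw, np.nan)))
    else:
        worst = 0.0
    raw = np.where(n_pos == 0, worst, raw)
    return pd.Series(raw, index=matrix.gene_ids, name="s_v_raw")


def minmax(values: Sequence[float] | np.ndarray | pd.Series) -> np.ndarray:
    """Min-max normalize to [0, 1]; an all-equal vector maps to 0.5."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return arr.copy()
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        return np.full_like(arr, 0.5)
    return (arr - lo) / (hi - lo)


def compute_subscores(matrix: ExpressionMatrix, config: ScoringConfig) -> pd.DataFrame:
    """All per-gene subscores for one (matrix, criteria) combination.

    Weight-independent: the sensitivity analysis calls this once and then
    re-combines under many weight triples.
    """
    matrix.require_scoring_shape()
    SUBSCORE_CALLS[0] += 1
    s_b = breadth_subscore(matrix, config.breadth_criterion)
    s_l_raw = level_subscore(matrix, config.level_criterion)
    s_v_raw = variation_subscore(matrix, config.variation_criterion)
    return pd.DataFrame(
        {
            "s_b": s_b,
            "s_l_raw": s_l_raw,
            "s_v_raw": s_v_raw,
            "s_l": minmax(s_l_raw),
            "s_v": minmax(s_v_raw),
        }
    )


def compose_from_subscores(
    subscores: pd.DataFrame, weights: tuple[float, float, float]
) -> ScoreTable:
    """Combine subscores under a weight triple into a ranked ScoreTable.

    Raw composite R(g) = w_b*s_b + w_l*s_l + w_v*s_v; the final score is
    minmax(R).  Percentile(g) is the percentage of genes scoring <= g.
    """
    w_b, w_l, w_v = weights
    raw = (
        w_b * subscores["s_b"].to_numpy()
        + w_l * subscores["s_l"].to_numpy()
        + w_v * subscores["s_v"].to_numpy()
    )
    score = minmax(raw)
    genes = np.asarray(subscores.index, dtype=object)
    # rank 1 = highest score; ties broken by ascending gene ID
    order = np.lexsort((genes, -score))
    n = len(genes)
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(1, n + 1)
    # percentile: fraction of genes with score <= own score (ties included)
    sorted_scores = np.sort(score)
    n_le = np.searchsorted(sorted_scores, score, side="right")
    percentile = 100.0 * n_le / n if n else np.array([])
    df = pd.DataFrame(
        {
            "s_b": subscores["s_b"],
            "s_l_raw": subscores["s_l_raw"],
            "s_v_raw": subscores["s_v_raw"],
            "s_l": subscores["s_l"],
            "s_v": subscores["s_v"],
            "score": score,
            "rank": rank,
            "percentile": percentile,
        },
        index=pd.Index(subscores.index, name="gene_id"),
    )
    return ScoreTable(df)


def compose_scores(matrix: ExpressionMatrix, config: ScoringConfig | None = None) -> ScoreTable:
    """Score every gene of a matrix under a configuration (defaults: Ubigen)."""
    config = config or ScoringConfig()
    return compose_from_subscores(compute_subscores(matrix, config), config.weights)
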