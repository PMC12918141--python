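"""GeTMM normalization of raw RNA-seq read counts.

GeTMM (gene-length-corrected trimmed mean of M-values) proceeds in three
steps:

1. counts are converted to reads per kilobase (RPK) using per-gene
   transcript lengths, removing gene-length bias;
2. per-sample scaling factors are estimated as a weighted trimmed mean of
   per-gene log2 expression ratios (M-values) against a reference sample,
   trimming the most extreme 30% of M-values and 5% of average log
   intensities (A-values), with delta-method precision weights;
3. each RPK column is divided by its column sum times the sample's scaling
   factor and multiplied by 1e6, yielding values comparable both within and
   between samples.

Scaling factors are rescaled so their geometric mean is exactly 1, making
them pure between-sample corrections.  M- and A-values here are computed on
the RPK values directly, so a sample that is a pure scalar multiple of the
reference yields a factor equal to that scalar (e.g. a 2x copy gives
factors (1/sqrt(2), sqrt(2)) after geometric-mean rescaling).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ubigen.formats_io import ExpressionMatrix, ValidationError

__all__ = [
    "GeneLengthTable",
    "TmmFactors",
    "counts_to_rpk",
    "tmm_factors",
    "getmm_normalize",
]


@dataclass
class GeneLengthTable:
    """Gene ID -> transcript length in base pairs (positive)."""

    lengths: pd.Series

    def __post_init__(self) -> None:
        s = pd.Series(self.lengths, dtype=float)
        if s.index.has_duplicates:
            raise ValidationError("duplicate gene IDs in length table")
        if (s <= 0).any() or not np.isfinite(s.to_numpy()).all():
            raise ValidationError("gene lengths must be positive and finite")
        self.lengths = s

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float] | pd.Series) -> "GeneLengthTable":
        return cls(pd.Series(mapping, dtype=float))

    def __len__(self) -> int:
        return len(self.lengths)


@dataclass
class TmmFactors:
    """Per-sample positive scaling factors with geometric mean 1."""

    factors: pd.Series

    def __post_init__(self) -> None:
        s = pd.Series(self.factors, dtype=float)
        if (s <= 0).any():
            raise ValidationError("TMM factors must be positive")
        log_mean = float(np.log(s.to_numpy()).mean())
        if abs(log_mean) > 1e-9:
            raise ValidationError(
                f"TMM factors must have geometric mean 1 (log-mean {log_mean:.3e})"
            )
        self.factors = s

    def __getitem__(self, sample_id: str) -> float:
        return float(self.factors[sample_id])


def _coerce_lengths(lengths: GeneLengthTable | pd.Series | Mapping[str, float]) -> pd.Series:
    if isinstance(lengths, GeneLengthTable):
        return lengths.lengths
    return GeneLengthTable.from_mapping(pd.Series(lengths, dtype=float)).lengths


def counts_to_rpk(
    counts: ExpressionMatrix,
    lengths: GeneLengthTable | pd.Series | Mapping[str, float],
) -> ExpressionMatrix:
    """Convert raw integer read counts to reads per kilobase.

    RPK(g, s) = count(g, s) / (length_bp(g) / 1000).  Genes without a length
    entry are dropped with a warning (the count is recorded in
    ``meta['dropped_no_length']``); non-integer inputs are rejected because
    they indicate already-normalized data.
    """
    length_s = _coerce_lengths(lengths)
    values = counts.values
    if not np.allclose(values, np.round(values), atol=1e-8):
        raise ValidationError(
            "counts_to_rpk expects raw integer read counts; "
            "found non-integer values (is the matrix already normalized?)"
        )
    covered = counts.data.index.intersection(length_s.index)
    n_dropped = counts.n_genes - len(covered)
    if len(covered) == 0:
        raise ValidationError("no gene in the count matrix has a length entry")
    if n_dropped:
        warnings.warn(
            f"counts_to_rpk: dropped {n_dropped} gene(s) without a length entry",
            stacklevel=2,
        )
    sub = counts.data.loc[covered]
    kb = length_s.loc[covered].to_numpy() / 1000.0
    rpk = sub.div(kb, axis=0)
    meta = dict(counts.meta)
    meta.update({"unit": "RPK", "dropped_no_length": n_dropped})
    return ExpressionMatrix(rpk, meta=meta)


def _pairwise_factor(
    y_s: np.ndarray, y_r: np.ndarray, lib_s: float, lib_r: float,
    trim_m: float, trim_a: float,
) -> float:
    """Weighted trimmed mean of M-values of one sample against the reference."""
    both = (y_s > 0) & (y_r > 0)
    ys, yr = y_s[both], y_r[both]
    if ys.size == 0:
        return 1.0
    m = np.log2(ys / yr)
    a = 0.5 * np.log2(ys * yr)
    n = m.size
    # symmetric rank-based double trim, as in the standard TMM procedure
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(m)
    ra = rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        return 1.0
    # delta-method precision weights (inverse approximate variance of M)
    w = (lib_s - ys) / (lib_s * ys) + (lib_r - yr) / (lib_r * yr)
    inv_var = 1.0 / np.maximum(w[keep], 1e-300)
    return float(2 ** np.average(m[keep], weights=inv_var))


def tmm_factors(
    rpk: ExpressionMatrix, trim_m: float = 0.30, trim_a: float = 0.05
) -> TmmFactors:
    """Estimate per-sample TMM scaling factors from an RPK matrix.

    The reference sample is the one whose upper quartile of positive values
    is closest to the mean upper quartile across samples (first sample on
    ties).  Factors are rescaled to geometric mean 1.
    """
    if rpk.n_samples < 2:
        raise ValidationError("TMM requires at least 2 samples")
    values = rpk.values
    col_pos = values > 0
    zero_cols = ~col_pos.any(axis=0)
    if zero_cols.any():
        bad = [s for s, z in zip(rpk.sample_ids, zero_cols) if z]
        raise ValidationError(f"sample(s) with all-zero values: {bad}")
    uq = np.array(
        [np.quantile(values[col_pos[:, j], j], 0.75) for j in range(rpk.n_samples)]
    )
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    lib = values.sum(axis=0)
    y_r = values[:, ref_idx]
    factors = np.ones(rpk.n_samples)
    for j in range(rpk.n_samples):
        if j == ref_idx:
            continue
        factors[j] = _pairwise_factor(values[:, j], y_r, lib[j], lib[ref_idx], trim_m, trim_a)
    factors /= np.exp(np.log(factors).mean())
    return TmmFactors(pd.Series(factors, index=rpk.sample_ids, name="tmm_factor"))


def getmm_normalize(
    counts: ExpressionMatrix,
    lengths: GeneLengthTable | pd.Series | Mapping[str, float],
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> ExpressionMatrix:
    """Full GeTMM chain: counts -> RPK -> TMM factors -> per-million scaling.

    value(g, s) = RPK(g, s) / (sum_g RPK(g, s) * factor(s)) * 1e6.
    For samples with identical composition the factors are 1 and each output
    column sums to exactly 1e6.
    """
    rpk = counts_to_rpk(counts, lengths)
    factors = tmm_factors(rpk, trim_m=trim_m, trim_a=trim_a)
    col_sums = rpk.values.sum(axis=0)
    denom = col_sums * factors.factors.to_numpy()
    out = rpk.data.div(denom, axis=1) * 1e6
    meta = dict(rpk.meta)
    meta.update({"normalization": "GeTMM", "unit": "GeTMM-CPM"})
    return ExpressionMatrix(out, meta=meta)
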