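"""Weight-sensitivity analysis of the composite score.

Every weight is varied by a relative fraction around its default (by
default +-20%, i.e. breadth in [0.40, 0.60], level in [0.20, 0.30],
variation in [-0.30, -0.20]) on an equally spaced per-axis grid; the full
factorial product (11 points per axis gives 1,331 triples) is evaluated and
the stability of the top-5% set is summarized as the size of the
intersection of all top sets divided by the top-set size.

Subscores do not depend on the weights, so they are computed once and only
the weighted combination is redone per triple.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product

import numpy as np

from ubigen.formats_io import ExpressionMatrix, ValidationError
from ubigen.scoring_core import ScoringConfig, compute_subscores, minmax

__all__ = ["WeightGrid", "weight_grid", "top_set_overlap"]


@dataclass
class WeightGrid:
    """Ordered list of (w_b, w_l, w_v) triples plus grid metadata."""

    triples: np.ndarray  # shape (n, 3)
    axis_ranges: tuple[tuple[float, float], ...]
    points_per_axis: int

    def __post_init__(self) -> None:
        arr = np.asarray(self.triples, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValidationError("weight grid must be an (n, 3) array")
        if (arr[:, 0] < 0).any() or (arr[:, 1] < 0).any() or (arr[:, 2] > 0).any():
            raise ValidationError("grid triples must satisfy w_b >= 0, w_l >= 0, w_v <= 0")
        self.triples = arr

    def __len__(self) -> int:
        return len(self.triples)


def weight_grid(
    defaults: tuple[float, float, float] = (0.5, 0.25, -0.25),
    rel_range: float = 0.20,
    points_per_axis: int = 11,
) -> WeightGrid:
    """Full factorial grid of weight triples around the defaults.

    Each axis spans ``default * (1 +- rel_range)`` with ``points_per_axis``
    equally spaced points (endpoints inclusive, ascending); the grid is the
    Cartesian product in lexicographic order.  One point per axis yields the
    single default triple.
    """
    if points_per_axis < 1:
        raise ValidationError("points_per_axis must be >= 1")
    if rel_range < 0:
        raise ValidationError("rel_range must be >= 0")
    axes = []
    ranges = []
    for d in defaults:
        lo, hi = sorted((d * (1 - rel_range), d * (1 + rel_range)))
        ranges.append((lo, hi))
        if points_per_axis == 1:
            axes.append(np.array([d]))
        else:
            axes.append(np.linspace(lo, hi, points_per_axis))
    triples = np.array(list(product(*axes)))
    return WeightGrid(triples, tuple(ranges), points_per_axis)


def top_set_overlap(
    matrix: ExpressionMatrix,
    config: ScoringConfig,
    grid: WeightGrid,
    top_fraction: float = 0.05,
    restrict_to: set[str] | None = None,
) -> float:
    """Fraction of the top set that survives every weight triple of the grid.

    ``overlap = |intersection over grid of top-k sets| / k`` with
    ``k = floor(top_fraction * N)``.  With ``restrict_to`` given (e.g. the
    sector-11 genes of a two-dataset comparison), each top set is first
    intersected with that set and the denominator becomes the size of the
    default-weight baseline top set intersected with it.
    """
    if len(grid) == 0:
        raise ValidationError("weight grid is empty")
    if not (0 < top_fraction <= 1):
        raise ValidationError(f"top_fraction must be in (0, 1], got {top_fraction}")
    sub = compute_subscores(matrix, config)
    s = sub[["s_b", "s_l", "s_v"]].to_numpy()
    genes = np.asarray(sub.index, dtype=object)
    n = len(genes)
    k = math.floor(top_fraction * n)
    if k == 0:
        raise ValidationError(f"top_fraction {top_fraction} selects 0 of {n} genes")

    def top_set(weights: np.ndarray) -> set[str]:
        raw = s @ weights
        order = np.lexsort((genes, -minmax(raw)))
        return set(genes[order[:k]])

    tops = [top_set(w) for w in grid.triples]
    inter = set.intersection(*tops)
    if restrict_to is None:
        return len(inter) / k
    baseline = top_set(np.asarray(config.weights, dtype=float)) & set(restrict_to)
    if not baseline:
        raise ValidationError("restrict_to is disjoint from the baseline top set")
    inter_restricted = set.intersection(*(t & set(restrict_to) for t in tops))
    return len(inter_restricted) / len(baseline)
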