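"""Concentration bounds for FracMinHash sketches and the recommended scale factor.

Under a strongly 2-universal hash family, membership of each element of A in
the sketch is an independent Bernoulli(s) event, so the sketch size X_A is a
Bernoulli sum with mean s|A| and a Chernoff bound gives

    Pr[ |X_A − s|A|| >= ε s|A| ] <= 2 exp(−s |A| ε² / 3),     0 < ε < 1.

Propagating that concentration through the ratio form of the set measures
yields, for the cosine similarity (and identically for Sorensen and
Bray–Curtis):

    Pr[ |cosθ' − cosθ| <= ε cosθ ] >= 1 − 6 exp(−s |A∩B| ε² / [3 (2+ε)²]),

and for Kulczynski-1 the same with 4 in place of 6 and min{|A∩B|, |AΔB|} in
place of |A∩B|.  Inverting the cosine bound for a desired tolerable error ε
and confidence level α gives the minimum safe scale factor

    s >= 3 (2+ε)² ln[6 / (1−α)] / (ε² · m),

where m = min{|A|, |B|} in the practical recommendation (the variant using
min{|A|, |B|, |A∩B|} is available via ``intersection_size``).  The (2+ε)²
factor already carries the ε ↔ δ substitution from the proof, so the
tables' "tolerable error δ" is passed directly as ``epsilon``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import pandas as pd

__all__ = [
    "ScaleQuery",
    "BoundReport",
    "expected_sketch_size",
    "sketch_size_tail_bound",
    "metric_error_bound",
    "recommend_scale_factor",
    "scale_factor_table",
    "round_half_up",
]

#: Metrics served by a probability bound (no unbiased estimator exists).
BOUNDED_METRICS = ("cosine", "kulczynski1", "sorensen", "bray_curtis")


class ScaleTheoryError(ValueError):
    pass


@dataclass(frozen=True)
class ScaleQuery:
    """A scale-factor question: how small an s still meets (ε, α)?

    Attributes
    ----------
    min_size
        min{|A|, |B|} over the pairs to be compared (positive integer).
    epsilon
        Tolerable relative error ε in (0, 1): the estimate should fall in
        (1 ± ε) times the true value.
    alpha
        Desired confidence α in [0, 1) that the estimate is within that window.
    """

    min_size: int
    epsilon: float
    alpha: float

    def __post_init__(self) -> None:
        if self.min_size < 1:
            raise ScaleTheoryError(f"min_size must be >= 1, got {self.min_size}")
        if not 0.0 < self.epsilon < 1.0:
            raise ScaleTheoryError(f"epsilon must lie in (0, 1), got {self.epsilon}")
        if not 0.0 <= self.alpha < 1.0:
            if self.alpha == 1.0:
                raise ScaleTheoryError(
                    "alpha = 1 demands certainty: no finite scale factor suffices"
                )
            raise ScaleTheoryError(f"alpha must lie in [0, 1), got {self.alpha}")


@dataclass(frozen=True)
class BoundReport:
    """A probability lower bound for a relative-error guarantee on one metric."""

    metric: str
    scale_factor: float
    intersection_size: float
    symmetric_difference_size: float | None
    epsilon: float
    probability_lower_bound: float


def expected_sketch_size(scale_factor: float, set_size: float) -> float:
    """E[X_A] = s |A|: the expected number of retained hashes."""
    if not 0.0 <= scale_factor <= 1.0:
        raise ScaleTheoryError(f"scale_factor must lie in [0, 1], got {scale_factor}")
    if set_size < 0:
        raise ScaleTheoryError(f"set size must be >= 0, got {set_size}")
    return scale_factor * set_size


def sketch_size_tail_bound(scale_factor: float, set_size: float, epsilon: float) -> float:
    """Chernoff upper bound on Pr[|X_A − s|A|| >= ε s|A|], clamped to <= 1.

    Equals min(1, 2 exp(−s |A| ε² / 3)); vacuous (1) when s|A| = 0.
    """
    if not 0.0 < epsilon < 1.0:
        raise ScaleTheoryError(f"epsilon must lie in (0, 1), got {epsilon}")
    mean = expected_sketch_size(scale_factor, set_size)
    return min(1.0, 2.0 * math.exp(-mean * epsilon**2 / 3.0))


def metric_error_bound(
    metric: str,
    scale_factor: float,
    intersection_size: float,
    epsilon: float,
    symmetric_difference_size: float | None = None,
) -> BoundReport:
    """Lower bound on the probability that the sketch estimate is within ±ε·truth.

    For cosine, Sorensen and Bray–Curtis the bound is
    1 − 6 exp(−s |A∩B| ε² / [3 (2+ε)²]); Kulczynski-1 replaces 6 by 4 and
    |A∩B| by min{|A∩B|, |AΔB|} (``symmetric_difference_size`` is required
    there).  The raw expression can be negative for tiny s·|A∩B| — the
    guarantee is then vacuous and is clamped to 0.
    """
    if metric not in BOUNDED_METRICS:
        raise ScaleTheoryError(
            f"no probability bound for {metric!r}; bounded metrics are {BOUNDED_METRICS}"
        )
    if not 0.0 < epsilon < 1.0:
        raise ScaleTheoryError(f"epsilon must lie in (0, 1), got {epsilon}")
    if intersection_size < 0:
        raise ScaleTheoryError("intersection_size must be >= 0")
    if metric == "kulczynski1":
        if symmetric_difference_size is None:
            raise ScaleTheoryError(
                "kulczynski1 needs symmetric_difference_size (|A Δ B|)"
            )
        coeff = 4.0
        size = min(intersection_size, symmetric_difference_size)
    else:
        coeff = 6.0
        size = intersection_size
    raw = 1.0 - coeff * math.exp(
        -scale_factor * size * epsilon**2 / (3.0 * (2.0 + epsilon) ** 2)
    )
    return BoundReport(
        metric=metric,
        scale_factor=scale_factor,
        intersection_size=intersection_size,
        symmetric_difference_size=symmetric_difference_size,
        epsilon=epsilon,
        probability_lower_bound=min(1.0, max(0.0, raw)),
    )


def recommend_scale_factor(
    min_size: int,
    epsilon: float,
    alpha: float,
    intersection_size: int | None = None,
) -> float:
    """Minimum scale factor meeting a (ε, α) accuracy target, capped at 1.

        s = min(1, 3 (2+ε)² ln[6/(1−α)] / (ε² m))

    with m = ``min_size`` = min{|A|, |B|}.  Passing ``intersection_size``
    switches to the sharper variant m = min{|A|, |B|, |A∩B|}; the default
    omits |A∩B| because for highly dissimilar sets a near-zero estimate
    already reports the dissimilarity faithfully.
    """
    q = ScaleQuery(min_size=min_size, epsilon=epsilon, alpha=alpha)
    m = q.min_size if intersection_size is None else min(q.min_size, intersection_size)
    if m < 1:
        raise ScaleTheoryError("effective minimum size must be >= 1")
    s = (
        3.0
        * (2.0 + q.epsilon) ** 2
        * math.log(6.0 / (1.0 - q.alpha))
        / (q.epsilon**2 * m)
    )
    return min(1.0, s)


def round_half_up(value: float, decimals: int = 4) -> float:
    """Round half away from zero at ``decimals`` places (table convention)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def scale_factor_table(
    min_size: int,
    epsilons: Sequence[float],
    alphas: Sequence[float],
    decimals: int | None = 4,
) -> pd.DataFrame:
    """Grid of recommended scale factors, rows ε ("tolerable error") × columns α.

    Values are rounded half-up to ``decimals`` places (pass ``None`` for raw
    values).  The grid is non-increasing down each column (larger tolerated
    error needs a smaller s) and non-decreasing along each row (higher
    confidence needs a larger s), with cells capped at 1.0.
    """
    rows = []
    for eps in epsilons:
        row = []
        for alpha in alphas:
            s = recommend_scale_factor(min_size, eps, alpha)
            row.append(s if decimals is None else round_half_up(s, decimals))
        rows.append(row)
    table = pd.DataFrame(rows, index=list(epsilons), columns=list(alphas))
    table.index.name = "epsilon"
    table.columns.name = "alpha"
    return table
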