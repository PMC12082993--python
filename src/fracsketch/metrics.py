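"""Set similarity/dissimilarity measures and their sketch-based estimators.

All measures here are functions of three cardinalities — |A|, |B| and
|A ∩ B| — of two finite sets:

    jaccard          |A∩B| / |A∪B|
    containment_ab   |A∩B| / |A|          (asymmetric; _ba uses |B|)
    cosine           |A∩B| / sqrt(|A|·|B|)    (Otsuka–Ochiai)
    kulczynski1      |A∩B| / |AΔB|
    kulczynski2      ( |A∩B|/|A| + |A∩B|/|B| ) / 2
    whittaker        1 − kulczynski2
    sorensen         2|A∩B| / (|A|+|B|)
    bray_curtis      1 − sorensen

Three evaluation paths are provided:

* :func:`metric_on_sets` — the exact value on raw sets (the ground truth);
* :func:`plug_in_metric` — the same formula with sketch cardinalities
  X_A, X_B, X_{A∩B} substituted for the true ones;
* :func:`corrected_estimate` — the plug-in value rescaled by
  1 / (1 − (1−s)^n), which removes the plug-in's downward bias for the
  Jaccard and containment indices (n = |A∪B| and |A| respectively), and by
  extension for Kulczynski-2 and the Whittaker distance, which are linear
  in the two containments.  No unbiased estimator is known for cosine,
  Kulczynski-1, Sorensen or Bray–Curtis; those are served by the
  probability bounds in :mod:`fracsketch.theory` instead.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

from .sketch import (
    Sketch,
    _require_compatible,
    estimate_cardinality,
    intersection_size,
)

logger = logging.getLogger(__name__)

#: All supported measures.
METRICS = (
    "jaccard",
    "containment_ab",
    "containment_ba",
    "cosine",
    "kulczynski1",
    "kulczynski2",
    "whittaker",
    "sorensen",
    "bray_curtis",
)

#: Measures for which a bias-corrected (unbiased) estimator exists.
CORRECTABLE_METRICS = (
    "jaccard",
    "containment_ab",
    "containment_ba",
    "kulczynski2",
    "whittaker",
)

#: Symmetric measures: value is invariant under swapping the two inputs.
SYMMETRIC_METRICS = (
    "jaccard",
    "cosine",
    "kulczynski1",
    "kulczynski2",
    "whittaker",
    "sorensen",
    "bray_curtis",
)

#: Diagonal value of each measure for a self-comparison.
SELF_SIMILARITY = {
    "jaccard": 1.0,
    "containment_ab": 1.0,
    "containment_ba": 1.0,
    "cosine": 1.0,
    "kulczynski1": math.inf,
    "kulczynski2": 1.0,
    "whittaker": 0.0,
    "sorensen": 1.0,
    "bray_curtis": 0.0,
}


class UndefinedMetricError(ValueError):
    """The metric's denominator is zero on exact sets (e.g. an empty operand)."""


class UnknownMetricError(ValueError):
    pass


@dataclass(frozen=True)
class MetricEstimate:
    """A named similarity/dissimilarity value and how it was obtained."""

    metric: str
    value: float
    corrected: bool
    inputs_note: dict


def _check_metric(metric: str) -> None:
    if metric not in METRICS:
        raise UnknownMetricError(f"unknown metric {metric!r}; choose from {METRICS}")


def _from_sizes(na: float, nb: float, nab: float, metric: str, strict: bool) -> float:
    """Evaluate a measure from the three cardinalities.

    With ``strict`` (exact sets) a zero denominator raises
    :class:`UndefinedMetricError`.  On the sketch path a zero denominator
    reports similarity 0 (dissimilarity 1) with a warning: an empty sketch
    of a non-empty set signals near-total dissimilarity at this scale, so 0
    is the faithful limiting value, but it carries no precision.
    """
    if metric == "kulczynski1":
        sym_diff = na + nb - 2 * nab
        if sym_diff == 0:
            # Identical sets: |AΔB| = 0. Report +inf explicitly rather than fail.
            return math.inf
        return nab / sym_diff

    if metric in ("jaccard",):
        denom = na + nb - nab
    elif metric == "containment_ab":
        denom = na
    elif metric == "containment_ba":
        denom = nb
    elif metric == "cosine":
        denom = math.sqrt(na * nb)
    elif metric in ("kulczynski2", "whittaker"):
        denom = min(na, nb)  # only for the zero test; formula handled below
    elif metric in ("sorensen", "bray_curtis"):
        denom = na + nb
    else:  # pragma: no cover
        raise UnknownMetricError(metric)

    if denom == 0:
        if strict:
            raise UndefinedMetricError(
                f"{metric} is undefined for an empty operand set"
            )
        warnings.warn(
            f"{metric}: empty sketch in a denominator; reporting the degenerate "
            "limiting value (similarity 0)"
        )
        return 1.0 if metric in ("whittaker", "bray_curtis") else 0.0

    if metric == "jaccard":
        return nab / denom
    if metric == "containment_ab":
        return nab / na
    if metric == "containment_ba":
        return nab / nb
    if metric == "cosine":
        return nab / denom
    if metric == "kulczynski2":
        return 0.5 * (nab / na + nab / nb)
    if metric == "whittaker":
        return 1.0 - 0.5 * (nab / na + nab / nb)
    if metric == "sorensen":
        return 2.0 * nab / (na + nb)
    # bray_curtis
    return 1.0 - 2.0 * nab / (na + nb)


def metric_on_sets(a: set, b: set, metric: str) -> MetricEstimate:
    """Exact value of a measure on two finite sets (the ground-truth oracle)."""
    _check_metric(metric)
    na, nb = len(a), len(b)
    nab = len(a & b)
    value = _from_sizes(na, nb, nab, metric, strict=True)
    return MetricEstimate(
        metric=metric,
        value=value,
        corrected=False,
        inputs_note={"size_a": na, "size_b": nb, "size_intersection": nab},
    )


def plug_in_metric(a: Sketch, b: Sketch, metric: str) -> MetricEstimate:
    """Measure evaluated on sketch cardinalities in place of the true ones.

    For scale factor 1 (and absent 64-bit collisions) this reduces to the
    exact value.  The plug-in Jaccard and containment are biased low by the
    factor 1 − (1−s)^n; see :func:`corrected_estimate`.
    """
    _check_metric(metric)
    _require_compatible(a, b)
    xa, xb = len(a), len(b)
    xab = intersection_size(a, b)
    value = _from_sizes(xa, xb, xab, metric, strict=False)
    return MetricEstimate(
        metric=metric,
        value=value,
        corrected=False,
        inputs_note={"sketch_a": xa, "sketch_b": xb, "sketch_intersection": xab},
    )


def correction_factor(scale_factor: float, n: float) -> float:
    """The debiasing multiplier 1 / (1 − (1−s)^n).

    Computed as ``-1 / expm1(n * log1p(-s))`` so that huge n (where
    (1−s)^n underflows) and tiny s are both handled accurately.  At s = 1
    the factor is exactly 1; n must be positive.
    """
    if scale_factor == 0:
        raise UndefinedMetricError("bias correction is undefined for scale_factor = 0")
    if n <= 0:
        raise UndefinedMetricError(
            f"bias correction needs a positive cardinality, got {n}"
        )
    if scale_factor == 1:
        return 1.0
    return -1.0 / math.expm1(n * math.log1p(-scale_factor))


def _cardinality(sketch: Sketch, label: str) -> float:
    if sketch.source_cardinality is not None:
        return float(sketch.source_cardinality)
    est = estimate_cardinality(sketch)
    logger.info(
        "exact cardinality of %s unavailable; using sketch estimate %.1f", label, est
    )
    return est


def corrected_estimate(
    a: Sketch,
    b: Sketch,
    metric: str,
    *,
    cardinality_a: float | None = None,
    cardinality_b: float | None = None,
    union_cardinality: float | None = None,
) -> MetricEstimate:
    """Bias-corrected estimator for Jaccard, containment, Kulczynski-2, Whittaker.

    The plug-in value is multiplied by 1/(1 − (1−s)^n) with n = |A∪B| for
    Jaccard and n = |A| (resp. |B|) for the containments; Kulczynski-2 is the
    mean of the two corrected containments and the Whittaker distance its
    complement.  Cardinalities default to the sketches' exact
    ``source_cardinality`` when present, otherwise to the X/s estimate
    (logged); explicit values may be passed to override.
    """
    _check_metric(metric)
    if metric not in CORRECTABLE_METRICS:
        raise UnknownMetricError(
            f"no unbiased estimator is available for {metric!r}; "
            f"correctable metrics are {CORRECTABLE_METRICS}"
        )
    _require_compatible(a, b)
    s = a.params.scale_factor
    if s == 0:
        raise UndefinedMetricError("bias correction is undefined for scale_factor = 0")

    note: dict = {
        "sketch_a": len(a),
        "sketch_b": len(b),
        "sketch_intersection": intersection_size(a, b),
    }

    if metric == "jaccard":
        if union_cardinality is None:
            from .sketch import union_size

            union_cardinality = union_size(a, b) / s
            logger.info(
                "exact |A ∪ B| unavailable; using sketch estimate %.1f",
                union_cardinality,
            )
        note["cardinality_union"] = float(union_cardinality)
        value = plug_in_metric(a, b, "jaccard").value * correction_factor(
            s, float(union_cardinality)
        )
    elif metric in ("containment_ab", "containment_ba"):
        base = a if metric == "containment_ab" else b
        card = cardinality_a if metric == "containment_ab" else cardinality_b
        card = _cardinality(base, metric[-2]) if card is None else float(card)
        note[f"cardinality_{metric[-2]}"] = card
        value = plug_in_metric(a, b, metric).value * correction_factor(s, card)
    else:  # kulczynski2 / whittaker
        ca = corrected_estimate(
            a, b, "containment_ab", cardinality_a=cardinality_a
        )
        cb = corrected_estimate(
            a, b, "containment_ba", cardinality_b=cardinality_b
        )
        note["cardinality_a"] = ca.inputs_note["cardinality_a"]
        note["cardinality_b"] = cb.inputs_note["cardinality_b"]
        k2 = 0.5 * (ca.value + cb.value)
        value = k2 if metric == "kulczynski2" else 1.0 - k2

    return MetricEstimate(metric=metric, value=value, corrected=True, inputs_note=note)
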