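"""Pairwise similarity/dissimilarity matrices over collections of sketches."""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from .hashing import SketchParams
from .metrics import (
    CORRECTABLE_METRICS,
    SELF_SIMILARITY,
    SYMMETRIC_METRICS,
    MetricEstimate,
    corrected_estimate,
    plug_in_metric,
)
from .sketch import IncompatibleSketchError, Sketch

PathLike = Union[str, "os.PathLike[str]"]


@dataclass(frozen=True)
class PairwiseMatrix:
    """A square matrix of one measure over a list of samples.

    The diagonal is the measure's self-comparison value (1 for similarities,
    0 for Bray–Curtis/Whittaker, +inf for Kulczynski-1).  For symmetric
    measures the matrix is symmetric; containment fills both ordered pairs.
    """

    labels: tuple[str, ...]
    metric: str
    values: np.ndarray
    corrected: bool
    params: SketchParams


def compute_pairwise_matrix(
    sketches: Sequence[Sketch],
    metric: str = "cosine",
    corrected: bool | None = None,
) -> PairwiseMatrix:
    """Evaluate a measure on every pair of sketches.

    ``corrected=None`` picks the default: the bias-corrected estimator for
    metrics that have one (Jaccard, containment, Kulczynski-2, Whittaker),
    the plug-in estimator otherwise.  All sketches must share identical
    parameters; a mismatch is reported with the offending sample names.
    """
    if len(sketches) < 2:
        raise ValueError("need at least two sketches for a pairwise matrix")
    params = sketches[0].params
    bad = [s.name for s in sketches if s.params != params]
    if bad:
        raise IncompatibleSketchError(
            "sketches built with different parameters: " + ", ".join(bad)
        )
    if corrected is None:
        corrected = metric in CORRECTABLE_METRICS
    if corrected and metric not in CORRECTABLE_METRICS:
        raise ValueError(f"no bias-corrected estimator exists for {metric!r}")

    n = len(sketches)
    values = np.full((n, n), SELF_SIMILARITY[metric], dtype=float)
    symmetric = metric in SYMMETRIC_METRICS

    def one(i: int, j: int) -> MetricEstimate:
        if corrected:
            return corrected_estimate(sketches[i], sketches[j], metric)
        return plug_in_metric(sketches[i], sketches[j], metric)

    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = one(i, j).value
            values[j, i] = values[i, j] if symmetric else one(j, i).value

    return PairwiseMatrix(
        labels=tuple(s.name for s in sketches),
        metric=metric,
        values=values,
        corrected=corrected,
        params=params,
    )


def write_matrix_csv(matrix: PairwiseMatrix, path: PathLike) -> None:
    """Write a full square matrix as CSV: label header row/column, 6 decimals.

    A leading comment line records the metric, the estimator variant and the
    sketch parameters; infinities (Kulczynski-1 self-comparisons) are written
    as the literal ``inf``.
    """
    p = matrix.params
    with open(path, "w") as fh:
        fh.write(
            f"# metric={matrix.metric} corrected={str(matrix.corrected).lower()} "
            f"k={p.k} scale_factor={p.scale_factor!r} hash_seed={p.hash_seed}\n"
        )
        fh.write("," + ",".join(matrix.labels) + "\n")
        for label, row in zip(matrix.labels, matrix.values):
            cells = ["inf" if math.isinf(v) else f"{v:.6f}" for v in row]
            fh.write(label + "," + ",".join(cells) + "\n")
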