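"""Monte-Carlo validation harness for FracMinHash estimation.

The experiments here emulate the validation protocol for the sketch-based
estimators on synthetic data: a universe of N integer elements (default 1M),
pairs of random subsets A and B of varying sizes, sketches at either a fixed
scale factor or the recommended one, and the fraction of repetitions in
which the sketch-based cosine lands within ±ε of the truth ("coverage").
The same machinery doubles as the Monte-Carlo oracle for the unbiasedness of
the corrected estimators and for the Chernoff concentration of sketch sizes.

Two element modes are provided:

* ``"hashed"`` (default) — universe elements are 8-byte little-endian
  integers pushed through the real MurmurHash3 path, exercising the full
  hashing stack;
* ``"uniform"`` — each trial draws a fresh idealized hash function, i.e.
  i.i.d. uniform 64-bit values per element.  This isolates estimator
  behaviour from hash quality and matches the theory's assumption of a hash
  function drawn fresh from a strongly universal family.

Reproducibility: every trial derives its generator from the tuple
(seed, cell_index, trial_index), so any cell can be replayed independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .hashing import HASH_RANGE_SIZE, SketchParams, hash_u64_elements
from .metrics import corrected_estimate, metric_on_sets, plug_in_metric
from .sketch import sketch_from_hashes
from .theory import recommend_scale_factor, sketch_size_tail_bound

__all__ = [
    "SimulationConfig",
    "CoverageResult",
    "UnbiasednessResult",
    "sample_set_pair",
    "run_cosine_trial",
    "coverage_experiment",
    "unbiasedness_experiment",
    "sketch_size_tail_experiment",
]

#: The 5×5 grid of set-size pairs used by the coverage experiments,
#: 100K–500K in steps of 100K.
DEFAULT_SET_SIZES: tuple[tuple[int, int], ...] = tuple(
    (a, b)
    for a in (100_000, 200_000, 300_000, 400_000, 500_000)
    for b in (100_000, 200_000, 300_000, 400_000, 500_000)
)


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Grid definition for a coverage experiment.

    Defaults reproduce the reference conditions: a 1M-element universe, set
    sizes 100K–500K, ±5% tolerance, 95% confidence in recommended-scale
    mode, 1000 repetitions per cell.
    """

    universe_size: int = 1_000_000
    set_sizes: tuple[tuple[int, int], ...] = DEFAULT_SET_SIZES
    scale_mode: str = "fixed"  # "fixed" or "recommended"
    fixed_s: float = 0.001
    epsilon: float = 0.05
    alpha: float = 0.95
    repetitions: int = 1000
    seed: int = 0
    element_mode: str = "hashed"  # "hashed" or "uniform"
    hash_seed: int = 42
    k: int = 21  # nominal k recorded on the synthetic sketches

    def __post_init__(self) -> None:
        if self.scale_mode not in ("fixed", "recommended"):
            raise SimulationError(f"unknown scale_mode {self.scale_mode!r}")
        if self.element_mode not in ("hashed", "uniform"):
            raise SimulationError(f"unknown element_mode {self.element_mode!r}")
        if self.repetitions < 1:
            raise SimulationError("repetitions must be >= 1")
        for na, nb in self.set_sizes:
            if na > self.universe_size or nb > self.universe_size:
                raise SimulationError(
                    f"set size ({na}, {nb}) exceeds universe size {self.universe_size}"
                )


@dataclass(frozen=True)
class CoverageResult:
    """Per-cell within-tolerance fractions from a coverage experiment."""

    config: SimulationConfig
    cells: tuple[dict, ...]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(list(self.cells))

    def fraction(self, size_a: int, size_b: int) -> float:
        for cell in self.cells:
            if cell["size_a"] == size_a and cell["size_b"] == size_b:
                return cell["fraction_within"]
        raise KeyError((size_a, size_b))


@dataclass(frozen=True)
class UnbiasednessResult:
    """Monte-Carlo mean of an estimator against the exact set value."""

    metric: str
    corrected: bool
    true_value: float
    mc_mean: float
    mc_se: float
    repetitions: int
    scale_factor: float
    analytic_plugin_factor: float  # E[plug-in]/truth predicted for Jaccard/containment


def sample_set_pair(
    universe_size: int, size_a: int, size_b: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Two independent uniform random subsets of {0, …, N−1}, without replacement."""
    if size_a > universe_size or size_b > universe_size:
        raise SimulationError(
            f"set sizes ({size_a}, {size_b}) exceed universe size {universe_size}"
        )
    a = rng.choice(universe_size, size=size_a, replace=False)
    b = rng.choice(universe_size, size=size_b, replace=False)
    return a, b


def _trial_rng(seed: int, cell_index: int, trial_index: int) -> np.random.Generator:
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence((seed, cell_index, trial_index)))
    )


def _intersection_count(universe_size: int, a: np.ndarray, b: np.ndarray) -> tuple[int, np.ndarray]:
    mask = np.zeros(universe_size, dtype=bool)
    mask[a] = True
    common = b[mask[b]]
    return int(common.size), common


def run_cosine_trial(
    a_elements: np.ndarray,
    b_elements: np.ndarray,
    scale_factor: float,
    epsilon: float,
    element_hashes: np.ndarray,
    params: SketchParams | None = None,
) -> tuple[float, float, bool]:
    """One trial: true cosine of (A, B) versus the sketch-based estimate.

    ``element_hashes`` maps every universe element to its 64-bit hash value
    (one realised hash function).  Returns (true, estimate, within), where
    ``within`` is |est − true| <= ε·true; for disjoint pairs the true cosine
    is 0 and the trial counts as within exactly when the estimate is 0.
    """
    if params is None:
        params = SketchParams(k=21, scale_factor=scale_factor)
    n = int(element_hashes.size)
    nab, _ = _intersection_count(n, a_elements, b_elements)
    true_cos = nab / math.sqrt(len(a_elements) * len(b_elements))

    sk_a = sketch_from_hashes(element_hashes[a_elements], params, name="A")
    sk_b = sketch_from_hashes(element_hashes[b_elements], params, name="B")
    est_cos = plug_in_metric(sk_a, sk_b, "cosine").value

    if true_cos == 0.0:
        within = est_cos == 0.0
    else:
        within = abs(est_cos - true_cos) <= epsilon * true_cos
    return true_cos, est_cos, within


def _hashed_universe(universe_size: int, hash_seed: int) -> np.ndarray:
    return hash_u64_elements(np.arange(universe_size, dtype=np.uint64), hash_seed)


def coverage_experiment(config: SimulationConfig) -> CoverageResult:
    """Run the full coverage grid: fraction of trials within ±ε per size pair.

    In ``"recommended"`` scale mode s is recomputed per cell from
    min(|A|, |B|) and the configured (ε, α); in ``"fixed"`` mode the same s
    is used everywhere.  Each cell also reports the number of trials whose
    sampled intersection was empty (where the tolerance window is degenerate).
    """
    fixed_table = None
    if config.element_mode == "hashed":
        fixed_table = _hashed_universe(config.universe_size, config.hash_seed)

    cells = []
    for ci, (na, nb) in enumerate(config.set_sizes):
        if config.scale_mode == "fixed":
            s = config.fixed_s
        else:
            s = recommend_scale_factor(min(na, nb), config.epsilon, config.alpha)
        params = SketchParams(k=config.k, scale_factor=s, hash_seed=config.hash_seed)
        n_within = 0
        n_zero = 0
        for t in range(config.repetitions):
            rng = _trial_rng(config.seed, ci, t)
            if fixed_table is not None:
                table = fixed_table
            else:
                table = rng.integers(
                    0, HASH_RANGE_SIZE, size=config.universe_size, dtype=np.uint64
                )
            a, b = sample_set_pair(config.universe_size, na, nb, rng)
            true_cos, _, within = run_cosine_trial(
                a, b, s, config.epsilon, table, params
            )
            n_within += within
            n_zero += true_cos == 0.0
        cells.append(
            {
                "size_a": na,
                "size_b": nb,
                "scale_factor": s,
                "fraction_within": n_within / config.repetitions,
                "n_zero_intersection": n_zero,
            }
        )
    return CoverageResult(config=config, cells=tuple(cells))


def unbiasedness_experiment(
    metric: str,
    size_a: int = 20_000,
    size_b: int = 20_000,
    universe_size: int = 1_000_000,
    scale_factor: float = 0.005,
    repetitions: int = 2000,
    seed: int = 0,
    corrected: bool = True,
) -> UnbiasednessResult:
    """Monte-Carlo mean of a sketch estimator against the exact set value.

    A single pair (A, B) is drawn once from the universe (so the true value
    is known exactly by construction); each repetition then draws a fresh
    idealized hash function — i.i.d. uniform 64-bit values on A ∪ B — builds
    both sketches, and evaluates the corrected (or plug-in) estimator with
    the exact cardinalities.  The estimator is unbiased when the Monte-Carlo
    mean matches the truth within sampling error; the plug-in Jaccard and
    containment are instead biased low by the factor 1 − (1−s)^n
    (n = |A∪B| resp. |A|), reported as ``analytic_plugin_factor``.
    """
    rng0 = _trial_rng(seed, 0, 0)
    a, b = sample_set_pair(universe_size, size_a, size_b, rng0)
    a_set, b_set = set(a.tolist()), set(b.tolist())
    true_value = metric_on_sets(a_set, b_set, metric).value

    union = np.union1d(a, b)
    idx_a = np.searchsorted(union, a)
    idx_b = np.searchsorted(union, b)
    n_union = int(union.size)

    params = SketchParams(k=21, scale_factor=scale_factor)
    values = np.empty(repetitions)
    for r in range(repetitions):
        rng = _trial_rng(seed, 1, r)
        h = rng.integers(0, HASH_RANGE_SIZE, size=n_union, dtype=np.uint64)
        sk_a = sketch_from_hashes(h[idx_a], params, source_cardinality=size_a)
        sk_b = sketch_from_hashes(h[idx_b], params, source_cardinality=size_b)
        if corrected:
            est = corrected_estimate(
                sk_a,
                sk_b,
                metric,
                cardinality_a=size_a,
                cardinality_b=size_b,
                union_cardinality=n_union,
            )
        else:
            est = plug_in_metric(sk_a, sk_b, metric)
        values[r] = est.value

    if metric == "jaccard":
        n_for_bias: float | None = n_union
    elif metric == "containment_ab":
        n_for_bias = size_a
    elif metric == "containment_ba":
        n_for_bias = size_b
    else:
        n_for_bias = None
    if n_for_bias is None:
        factor = math.nan
    elif scale_factor == 1.0:
        factor = 1.0
    else:
        factor = float(-math.expm1(n_for_bias * math.log1p(-scale_factor)))

    return UnbiasednessResult(
        metric=metric,
        corrected=corrected,
        true_value=true_value,
        mc_mean=float(values.mean()),
        mc_se=float(values.std(ddof=1) / math.sqrt(repetitions)),
        repetitions=repetitions,
        scale_factor=scale_factor,
        analytic_plugin_factor=factor,
    )


def sketch_size_tail_experiment(
    scale_factor: float,
    set_size: int,
    epsilons: Sequence[float],
    repetitions: int = 5000,
    seed: int = 0,
) -> list[dict]:
    """Empirical sketch-size tail frequencies against the Chernoff bound.

    Each repetition assigns fresh idealized uniform hashes to ``set_size``
    elements and counts how many fall at or below the threshold; for each ε
    the observed frequency of |X − s·n| >= ε·s·n is reported next to the
    bound 2·exp(−s·n·ε²/3).  The bound should dominate the observation.
    """
    params = SketchParams(k=21, scale_factor=scale_factor)
    t = params.threshold
    rng = _trial_rng(seed, 0, 0)
    sizes = np.empty(repetitions, dtype=np.int64)
    chunk = max(1, int(5_000_000 // max(set_size, 1)))
    done = 0
    while done < repetitions:
        m = min(chunk, repetitions - done)
        draws = rng.integers(0, HASH_RANGE_SIZE, size=(m, set_size), dtype=np.uint64)
        if t >= HASH_RANGE_SIZE:
            sizes[done : done + m] = set_size
        else:
            sizes[done : done + m] = (draws <= np.uint64(t)).sum(axis=1)
        done += m

    mean = scale_factor * set_size
    out = []
    for eps in epsilons:
        freq = float(np.mean(np.abs(sizes - mean) >= eps * mean))
        out.append(
            {
                "scale_factor": scale_factor,
                "set_size": set_size,
                "epsilon": eps,
                "empirical_tail_frequency": freq,
                "chernoff_bound": sketch_size_tail_bound(scale_factor, set_size, eps),
            }
        )
    return out
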