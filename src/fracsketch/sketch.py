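"""FracMinHash sketches: construction, set operations, and JSON signatures.

A FracMinHash sketch of a k-mer set A keeps the hash values of the members
that fall at or below a fraction s of the 64-bit hash range:

    FRAC_s(A) = { h(a) : a in A, h(a) <= floor(s * H) },   H = 2**64.

The sketch is a uniform random subsample of A's hashes, so its size
concentrates around s * |A| and set operations on sketches (intersection,
union) estimate the corresponding operations on the full sets.  Sketches
here are plain sets of hashes — no abundances — stored as sorted numpy
uint64 arrays.

Sketches are serialised to a small JSON signature format with hash values as
decimal strings, so that readers without exact 64-bit integer support cannot
silently corrupt them.
"""

from __future__ import annotations

import gzip
import io
import json
import logging
import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Union

import numpy as np
from Bio import SeqIO

from .hashing import (
    HASH_RANGE_SIZE,
    SketchParameterError,
    SketchParams,
    hash_kmer,
    stream_kmers,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, "os.PathLike[str]"]


class IncompatibleSketchError(ValueError):
    """Two sketches were built with different parameters and cannot be compared."""


class SignatureFormatError(ValueError):
    """A signature file is malformed or carries out-of-range values."""


@dataclass(frozen=True)
class Sketch:
    """A FracMinHash sketch: sorted distinct 64-bit hashes plus parameters.

    Attributes
    ----------
    hashes
        Sorted, strictly increasing uint64 array; every value is at or below
        the acceptance threshold ``floor(s * 2**64)``.
    params
        The :class:`~fracsketch.hashing.SketchParams` used to build it.
    name
        Free-text sample label (defaults to the source file name).
    source_cardinality
        Exact number of distinct canonical k-mers in the source set, when it
        was tracked at build time; used by the bias-corrected estimators.
    """

    hashes: np.ndarray
    params: SketchParams
    name: str = ""
    source_cardinality: int | None = None

    def __post_init__(self) -> None:
        h = np.ascontiguousarray(self.hashes, dtype=np.uint64)
        object.__setattr__(self, "hashes", h)
        if h.size and not np.all(h[1:] > h[:-1]):
            raise SketchParameterError("sketch hashes must be sorted and distinct")
        if h.size:
            t = self.params.threshold
            if t < HASH_RANGE_SIZE and int(h[-1]) > t:
                raise SketchParameterError(
                    f"hash value {int(h[-1])} exceeds threshold {t}"
                )

    def __len__(self) -> int:
        return int(self.hashes.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Sketch):
            return NotImplemented
        return (
            self.params == other.params
            and self.name == other.name
            and self.source_cardinality == other.source_cardinality
            and np.array_equal(self.hashes, other.hashes)
        )


def _require_compatible(a: Sketch, b: Sketch) -> None:
    if a.params != b.params:
        diffs = [
            f for f in ("k", "scale_factor", "hash_seed")
            if getattr(a.params, f) != getattr(b.params, f)
        ]
        raise IncompatibleSketchError(
            f"sketches are not comparable; differing parameter(s): {', '.join(diffs)} "
            f"({a.params} vs {b.params})"
        )


# --------------------------------------------------------------------------
# Construction
# --------------------------------------------------------------------------

def build_sketch(
    kmers: Iterable[str],
    params: SketchParams,
    track_cardinality: bool = False,
    name: str = "",
) -> Sketch:
    """Build a sketch from a stream of canonical k-mers.

    Duplicate k-mers are collapsed; a k-mer's hash enters the sketch iff it
    is at or below ``floor(s * 2**64)``.  With ``track_cardinality`` the
    exact number of distinct k-mers seen is recorded on the sketch, which the
    bias corrections prefer over the sketch-based cardinality estimate.
    """
    threshold = params.threshold
    seen: set[str] = set()
    kept: set[int] = set()
    n_distinct = 0
    for kmer in kmers:
        if kmer in seen:
            continue
        seen.add(kmer)
        n_distinct += 1
        v = hash_kmer(kmer, params)
        if v <= threshold:
            kept.add(v)
    hashes = np.fromiter(kept, dtype=np.uint64, count=len(kept))
    hashes.sort()
    return Sketch(
        hashes=hashes,
        params=params,
        name=name,
        source_cardinality=n_distinct if track_cardinality else None,
    )


def sketch_from_hashes(
    hashes: np.ndarray,
    params: SketchParams,
    name: str = "",
    source_cardinality: int | None = None,
) -> Sketch:
    """Build a sketch from precomputed 64-bit hash values.

    Values above the acceptance threshold are dropped; the rest are sorted
    and deduplicated.  This is the fast path used by the simulation harness,
    where hashes of a synthetic universe are computed in bulk.
    """
    h = np.ascontiguousarray(hashes, dtype=np.uint64)
    t = params.threshold
    if t >= HASH_RANGE_SIZE:
        kept = h
    elif t < 0:  # pragma: no cover - threshold is always >= 0
        kept = h[:0]
    else:
        kept = h[h <= np.uint64(t)]
    return Sketch(
        hashes=np.unique(kept),
        params=params,
        name=name,
        source_cardinality=source_cardinality,
    )


def _open_maybe_gzip(path: PathLike) -> io.TextIOWrapper:
    raw = open(path, "rb")
    magic = raw.read(2)
    raw.seek(0)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(raw))  # type: ignore[arg-type]
    return io.TextIOWrapper(raw)


def sketch_from_file(
    path: PathLike,
    params: SketchParams,
    track_cardinality: bool = False,
    name: str | None = None,
) -> Sketch:
    """Sketch the union of canonical k-mers from a FASTA or FASTQ file.

    The format is auto-detected from the first non-blank character ('>' for
    FASTA, '@' for FASTQ) and gzip compression from the magic bytes.  FASTQ
    quality strings are ignored.  An empty file yields an empty sketch with
    a warning.
    """
    if name is None:
        name = os.path.basename(os.fspath(path))
    with _open_maybe_gzip(path) as handle:
        first = ""
        for line in handle:
            if line.strip():
                first = line.strip()[0]
                break
        handle.seek(0)
        if first == "":
            warnings.warn(f"{path}: empty sequence file; producing an empty sketch")
            return build_sketch((), params, track_cardinality, name=name)
        if first == ">":
            fmt = "fasta"
        elif first == "@":
            fmt = "fastq"
        else:
            raise SignatureFormatError(
                f"{path}: not a FASTA or FASTQ file (first character {first!r})"
            )

        def all_kmers() -> Iterable[str]:
            for record in SeqIO.parse(handle, fmt):
                yield from stream_kmers(str(record.seq), params)

        return build_sketch(all_kmers(), params, track_cardinality, name=name)


# --------------------------------------------------------------------------
# Set operations and cardinality
# --------------------------------------------------------------------------

def intersection_size(a: Sketch, b: Sketch) -> int:
    """Number of hash values present in both sketches (X_{A∩B})."""
    _require_compatible(a, b)
    return int(np.intersect1d(a.hashes, b.hashes, assume_unique=True).size)


def union_size(a: Sketch, b: Sketch) -> int:
    """Number of distinct hash values across both sketches (X_{A∪B})."""
    _require_compatible(a, b)
    return len(a) + len(b) - intersection_size(a, b)


def estimate_cardinality(sketch: Sketch) -> float:
    """Estimate |A| as X_A / s, the inverse of E[X_A] = s |A|."""
    s = sketch.params.scale_factor
    if s == 0:
        raise SketchParameterError(
            "cardinality is undefined for scale_factor = 0 (empty sketch by construction)"
        )
    return len(sketch) / s


# --------------------------------------------------------------------------
# JSON signature format
# --------------------------------------------------------------------------

def write_signature(sketch: Sketch, path: PathLike) -> None:
    """Write a sketch as a JSON signature.

    Hash values are stored as decimal strings, sorted ascending, to survive
    JSON readers that parse numbers as 64-bit floats.
    """
    doc = {
        "name": sketch.name,
        "k": sketch.params.k,
        "scale_factor": sketch.params.scale_factor,
        "hash_seed": sketch.params.hash_seed,
        "hashes": [str(int(v)) for v in sketch.hashes],
    }
    if sketch.source_cardinality is not None:
        doc["source_cardinality"] = sketch.source_cardinality
    with open(path, "w") as fh:
        json.dump(doc, fh)
        fh.write("\n")


def read_signature(path: PathLike) -> Sketch:
    """Read a sketch written by :func:`write_signature`.

    Hash sets are compared as sets on read: the file's ordering is not
    trusted, so signatures from writers using the strict (<) rather than the
    inclusive (<=) boundary convention load identically — the two conventions
    can only differ on the single boundary value.
    """
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SignatureFormatError(f"{path}: malformed JSON ({exc})") from exc
    for fld in ("name", "k", "scale_factor", "hash_seed", "hashes"):
        if fld not in doc:
            raise SignatureFormatError(f"{path}: missing required field {fld!r}")
    try:
        params = SketchParams(
            k=int(doc["k"]),
            scale_factor=float(doc["scale_factor"]),
            hash_seed=int(doc["hash_seed"]),
        )
    except SketchParameterError as exc:
        raise SignatureFormatError(f"{path}: {exc}") from exc
    values = np.array(sorted(int(v) for v in doc["hashes"]), dtype=np.uint64)
    if values.size and (int(values.min()) < 0 or int(values.max()) >= HASH_RANGE_SIZE):
        raise SignatureFormatError(f"{path}: field 'hashes' has out-of-range values")
    card = doc.get("source_cardinality")
    try:
        return Sketch(
            hashes=values,
            params=params,
            name=str(doc["name"]),
            source_cardinality=None if card is None else int(card),
        )
    except SketchParameterError as exc:
        raise SignatureFormatError(f"{path}: {exc}") from exc
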