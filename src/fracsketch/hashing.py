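"""Canonical k-mer extraction and 64-bit MurmurHash3 hashing.

FracMinHash sketching decides membership of a k-mer in a sketch purely from
its hash value, so the hash semantics are part of the on-disk sketch contract:
two tools produce identical sketches only if they canonicalize k-mers the same
way and hash the same bytes with the same function, variant and seed.  This
module reproduces the convention shared by sourmash and frac-kmc:

* a k-mer is replaced by the lexicographically smaller of itself and its
  reverse complement (strand-invariant "canonical" form);
* the canonical k-mer's uppercase ASCII bytes are hashed with MurmurHash3
  x64_128 and the first 64-bit word of the digest is kept, seed 42 by default.

MurmurHash3 is implemented here directly (there is no guarantee of
2-universality, but empirically its output is uniform enough for the
concentration results to hold; the test suite checks uniformity).  A
vectorised variant for 8-byte little-endian integer keys is provided for the
simulation harness, which hashes synthetic integer universes at scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator

import numpy as np

#: Size of the hash range H.  Hash values are unsigned 64-bit integers in
#: [0, H); a sketch with scale factor s keeps values <= floor(s * H).
HASH_RANGE_SIZE: int = 1 << 64

#: Default MurmurHash3 seed, matching sourmash and frac-kmc.
DEFAULT_HASH_SEED: int = 42

_U64_MASK = (1 << 64) - 1


class InvalidKmerError(ValueError):
    """A k-mer contains characters outside {A, C, G, T}."""


class SketchParameterError(ValueError):
    """Sketching parameters are out of their legal range."""


@dataclass(frozen=True)
class SketchParams:
    """Hashing/sketching configuration shared by a family of sketches.

    Parameters
    ----------
    k
        k-mer length, >= 1.
    scale_factor
        Fraction s of the hash range retained, in [0, 1].  ``s = 0`` yields
        empty sketches; ``s = 1`` retains every distinct k-mer's hash.
        The sourmash convention ``scaled = S`` corresponds to ``s = 1/S``.
    hash_seed
        MurmurHash3 seed (unsigned 32-bit).  Sketches are only comparable
        when built with identical ``(k, scale_factor, hash_seed)``.
    """

    k: int
    scale_factor: float
    hash_seed: int = DEFAULT_HASH_SEED

    def __post_init__(self) -> None:
        if not isinstance(self.k, int) or self.k < 1:
            raise SketchParameterError(f"k must be a positive integer, got {self.k!r}")
        if not 0.0 <= self.scale_factor <= 1.0:
            raise SketchParameterError(
                f"scale_factor must lie in [0, 1], got {self.scale_factor!r}"
            )
        if not 0 <= self.hash_seed < (1 << 32):
            raise SketchParameterError(
                f"hash_seed must be an unsigned 32-bit integer, got {self.hash_seed!r}"
            )

    @property
    def threshold(self) -> int:
        """Acceptance threshold T = floor(s * H); hashes with v <= T are kept."""
        return scaled_threshold(self.scale_factor)


def scaled_threshold(scale_factor: float) -> int:
    """floor(s * H) for H = 2**64, clamped to [0, H]."""
    if not 0.0 <= scale_factor <= 1.0:
        raise SketchParameterError(
            f"scale_factor must lie in [0, 1], got {scale_factor!r}"
        )
    return min(HASH_RANGE_SIZE, math.floor(scale_factor * float(HASH_RANGE_SIZE)))


# --------------------------------------------------------------------------
# Canonical k-mers
# --------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = frozenset("ACGT")


def reverse_complement(kmer: str) -> str:
    """Reverse complement of an uppercase ACGT string."""
    return kmer.translate(_COMPLEMENT)[::-1]


def canonicalize(kmer: str) -> str:
    """Return the lexicographically smaller of a k-mer and its reverse complement.

    The input is uppercased first; any character outside {A, C, G, T} raises
    :class:`InvalidKmerError`.  The map is idempotent and strand-invariant:
    ``canonicalize(x) == canonicalize(reverse_complement(x))``.
    """
    kmer = kmer.upper()
    if not _VALID.issuperset(kmer):
        bad = sorted(set(kmer) - _VALID)
        raise InvalidKmerError(f"k-mer {kmer!r} contains non-ACGT characters {bad}")
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def stream_kmers(sequence: str, params: SketchParams) -> Iterator[str]:
    """Yield the canonical form of every valid length-k window of ``sequence``.

    Input is uppercased; windows containing any character outside {A, C, G, T}
    (ambiguity codes, gaps) are skipped rather than substituted, the common
    k-mer-counter convention.  Sequences shorter than k yield nothing.
    """
    k = params.k
    seq = sequence.upper()
    n = len(seq)
    if n < k:
        return
    # Rightmost invalid position seen so far; a window [i, i+k) is clean
    # only once the scan has moved k positions past it.
    last_bad = -1
    for i, ch in enumerate(seq):
        if ch not in _VALID:
            last_bad = i
        start = i - k + 1
        if start > last_bad and start >= 0:
            kmer = seq[start : i + 1]
            rc = reverse_complement(kmer)
            yield kmer if kmer <= rc else rc


# --------------------------------------------------------------------------
# MurmurHash3 x64_128 (first 64-bit word)
# --------------------------------------------------------------------------

_C1 = 0x87C37B91114253D5
_C2 = 0x4CF5AD432745937F


def _rotl64(x: int, r: int) -> int:
    return ((x << r) | (x >> (64 - r))) & _U64_MASK


def _fmix64(k: int) -> int:
    k ^= k >> 33
    k = (k * 0xFF51AFD7ED558CCD) & _U64_MASK
    k ^= k >> 33
    k = (k * 0xC4CEB9FE1A85EC53) & _U64_MASK
    k ^= k >> 33
    return k


def murmurhash3_x64_128(data: bytes, seed: int = 0) -> tuple[int, int]:
    """MurmurHash3 x64_128 digest of ``data`` as two unsigned 64-bit words.

    Pure-Python port of the public-domain reference algorithm; validated
    against the SMHasher verification value in the test suite.
    """
    length = len(data)
    nblocks = length // 16
    h1 = seed & _U64_MASK
    h2 = seed & _U64_MASK

    for b in range(nblocks):
        k1 = int.from_bytes(data[b * 16 : b * 16 + 8], "little")
        k2 = int.from_bytes(data[b * 16 + 8 : b * 16 + 16], "little")

        k1 = (k1 * _C1) & _U64_MASK
        k1 = _rotl64(k1, 31)
        k1 = (k1 * _C2) & _U64_MASK
        h1 ^= k1
        h1 = _rotl64(h1, 27)
        h1 = (h1 + h2) & _U64_MASK
        h1 = (h1 * 5 + 0x52DCE729) & _U64_MASK

        k2 = (k2 * _C2) & _U64_MASK
        k2 = _rotl64(k2, 33)
        k2 = (k2 * _C1) & _U64_MASK
        h2 ^= k2
        h2 = _rotl64(h2, 31)
        h2 = (h2 + h1) & _U64_MASK
        h2 = (h2 * 5 + 0x38495AB5) & _U64_MASK

    tail = data[nblocks * 16 :]
    k1 = 0
    k2 = 0
    if len(tail) > 8:
        k2 = int.from_bytes(tail[8:], "little")
        k2 = (k2 * _C2) & _U64_MASK
        k2 = _rotl64(k2, 33)
        k2 = (k2 * _C1) & _U64_MASK
        h2 ^= k2
    if tail:
        k1 = int.from_bytes(tail[:8], "little")
        k1 = (k1 * _C1) & _U64_MASK
        k1 = _rotl64(k1, 31)
        k1 = (k1 * _C2) & _U64_MASK
        h1 ^= k1

    h1 ^= length
    h2 ^= length
    h1 = (h1 + h2) & _U64_MASK
    h2 = (h2 + h1) & _U64_MASK
    h1 = _fmix64(h1)
    h2 = _fmix64(h2)
    h1 = (h1 + h2) & _U64_MASK
    h2 = (h2 + h1) & _U64_MASK
    return h1, h2


def hash_kmer(kmer: str, params: SketchParams) -> int:
    """Hash a canonical k-mer to an unsigned 64-bit value.

    The value is the first 64-bit word of the MurmurHash3 x64_128 digest of
    the k-mer's ASCII bytes with ``params.hash_seed`` — the sourmash/frac-kmc
    hash.  The caller is expected to pass canonical k-mers; canonicalization
    is not re-applied here.
    """
    return murmurhash3_x64_128(kmer.encode("ascii"), params.hash_seed)[0]


def hash_u64_elements(elements: np.ndarray, seed: int = DEFAULT_HASH_SEED) -> np.ndarray:
    """Vectorised MurmurHash3 x64_128 (first word) of 8-byte integer keys.

    Each element is treated as its 8-byte little-endian encoding, exactly as
    if ``murmurhash3_x64_128(int(e).to_bytes(8, "little"), seed)[0]`` were
    called per element.  Used by the simulation harness to push synthetic
    integer universes through the real hash path at numpy speed.
    """
    e = np.ascontiguousarray(elements, dtype=np.uint64)
    c1 = np.uint64(_C1)
    c2 = np.uint64(_C2)
    h1 = np.full(e.shape, seed, dtype=np.uint64)
    h2 = h1.copy()

    def rotl(x: np.ndarray, r: int) -> np.ndarray:
        return (x << np.uint64(r)) | (x >> np.uint64(64 - r))

    # 8-byte keys have no 16-byte body: the whole key is the k1 tail.
    k1 = e * c1
    k1 = rotl(k1, 31)
    k1 = k1 * c2
    h1 = h1 ^ k1

    length = np.uint64(8)
    h1 = h1 ^ length
    h2 = h2 ^ length
    h1 = h1 + h2
    h2 = h2 + h1

    def fmix(k: np.ndarray) -> np.ndarray:
        k = k ^ (k >> np.uint64(33))
        k = k * np.uint64(0xFF51AFD7ED558CCD)
        k = k ^ (k >> np.uint64(33))
        k = k * np.uint64(0xC4CEB9FE1A85EC53)
        k = k ^ (k >> np.uint64(33))
        return k

    h1 = fmix(h1)
    h2 = fmix(h2)
    h1 = h1 + h2
    return h1
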