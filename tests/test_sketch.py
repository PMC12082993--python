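"""Sketch construction, set operations, file sketching and signatures."""

import json
import math

import numpy as np
import pytest

from fracsketch import (
    HASH_RANGE_SIZE,
    IncompatibleSketchError,
    SignatureFormatError,
    Sketch,
    SketchParameterError,
    SketchParams,
    build_sketch,
    estimate_cardinality,
    hash_u64_elements,
    intersection_size,
    read_signature,
    sketch_from_file,
    sketch_from_hashes,
    stream_kmers,
    union_size,
    write_signature,
)

from conftest import int_sketch


def random_kmers(n, k, seed):
    rng = np.random.default_rng(seed)
    out = set()
    while len(out) < n:
        out.add("".join(rng.choice(list("ACGT"), k)))
    return out


class TestBuildSketch:
    def test_scale_zero_is_empty(self):
        params = SketchParams(k=5, scale_factor=0.0)
        assert len(build_sketch(["ACGTA", "TTTTT"], params)) == 0

    def test_scale_one_keeps_every_distinct_kmer(self):
        kmers = {kmer for kmer in random_kmers(1000, 21, seed=3)}
        canon = {min(k, k.translate(str.maketrans("ACGT", "TGCA"))[::-1]) for k in kmers}
        params = SketchParams(k=21, scale_factor=1.0)
        sk = build_sketch(kmers, params, track_cardinality=True)
        assert len(sk) == len(canon)
        assert sk.source_cardinality == len(canon)

    def test_duplicates_collapse(self):
        params = SketchParams(k=3, scale_factor=1.0)
        assert len(build_sketch(["ACG", "ACG", "GTA", "ACG"], params)) == 2

    def test_mean_size_matches_expectation_over_hash_functions(self):
        """E[X_A] = s|A|: 10,000 elements at s=0.1 over 200 hash seeds."""
        n, s = 10_000, 0.1
        elements = np.arange(n, dtype=np.uint64)
        sizes = []
        for seed in range(200):
            params = SketchParams(k=21, scale_factor=s, hash_seed=seed)
            sizes.append(len(sketch_from_hashes(hash_u64_elements(elements, seed), params)))
        tol = 3 * math.sqrt(n * s * (1 - s) / 200)
        assert abs(np.mean(sizes) - s * n) < tol

    def test_scale_monotonicity(self):
        """hashes(s1) is a subset of hashes(s2) for s1 <= s2, same input."""
        small = int_sketch(range(5000), scale_factor=0.05)
        large = int_sketch(range(5000), scale_factor=0.2)
        assert np.isin(small.hashes, large.hashes).all()

    def test_rejects_unsorted_or_overflowing_hashes(self):
        params = SketchParams(k=3, scale_factor=0.5)
        with pytest.raises(SketchParameterError):
            Sketch(hashes=np.array([5, 3], dtype=np.uint64), params=params)
        with pytest.raises(SketchParameterError):
            Sketch(hashes=np.array([HASH_RANGE_SIZE - 1], dtype=np.uint64), params=params)


class TestSetOperations:
    def test_against_brute_force_sets(self):
        rng = np.random.default_rng(11)
        a = set(rng.integers(0, 500, 200).tolist())
        b = set(rng.integers(0, 500, 200).tolist())
        sa, sb = int_sketch(a), int_sketch(b)
        assert intersection_size(sa, sb) == len(a & b)
        assert union_size(sa, sb) == len(a | b)
        assert union_size(sa, sb) == len(sa) + len(sb) - intersection_size(sa, sb)

    def test_identity_and_disjoint(self):
        sa = int_sketch(range(100))
        sb = int_sketch(range(100, 200))
        assert intersection_size(sa, sa) == len(sa)
        assert union_size(sa, sa) == len(sa)
        assert intersection_size(sa, sb) == 0
        assert union_size(sa, sb) == len(sa) + len(sb)

    def test_parameter_mismatch_names_field(self):
        a = int_sketch(range(10), scale_factor=1.0)
        b = int_sketch(range(10), scale_factor=0.5)
        with pytest.raises(IncompatibleSketchError, match="scale_factor"):
            intersection_size(a, b)
        c = int_sketch(range(10), hash_seed=7)
        with pytest.raises(IncompatibleSketchError, match="hash_seed"):
            union_size(a, c)


class TestEstimateCardinality:
    def test_exact_at_scale_one(self):
        assert estimate_cardinality(int_sketch(range(500))) == 500

    def test_empty_sketch(self):
        assert estimate_cardinality(int_sketch([], scale_factor=0.5)) == 0

    def test_undefined_at_scale_zero(self):
        with pytest.raises(SketchParameterError):
            estimate_cardinality(int_sketch(range(10), scale_factor=0.0))

    def test_monte_carlo_mean(self):
        """X_A/s over 500 idealized hash draws centres on |A| = 100,000."""
        n, s, reps = 100_000, 0.01, 500
        rng = np.random.default_rng(42)
        params = SketchParams(k=21, scale_factor=s)
        estimates = [
            estimate_cardinality(
                sketch_from_hashes(
                    rng.integers(0, HASH_RANGE_SIZE, n, dtype=np.uint64), params
                )
            )
            for _ in range(reps)
        ]
        se = math.sqrt((1 - s) * n / s) / math.sqrt(reps)
        assert abs(np.mean(estimates) - n) < 3 * se


class TestFileSketching:
    def test_fasta_matches_hand_enumeration(self, write_fasta):
        params = SketchParams(k=3, scale_factor=1.0)
        path = write_fasta([("r1", "ACGTACGT")])
        sk = sketch_from_file(path, params, track_cardinality=True)
        expected = set(stream_kmers("ACGTACGT", params))
        assert len(sk) == len(expected)
        assert sk.source_cardinality == len(expected)
        assert sk.name == path.name

    def test_fastq_equals_fasta(self, write_fasta, write_fastq):
        params = SketchParams(k=5, scale_factor=1.0)
        fa = sketch_from_file(write_fasta([("r", "ACGTACGTGGTT")]), params)
        fq = sketch_from_file(write_fastq([("r", "ACGTACGTGGTT")]), params)
        assert np.array_equal(fa.hashes, fq.hashes)

    def test_gzip_transparent(self, write_fasta):
        params = SketchParams(k=5, scale_factor=1.0)
        plain = sketch_from_file(write_fasta([("r", "ACGTACGTGGTT")]), params)
        gz = sketch_from_file(
            write_fasta([("r", "ACGTACGTGGTT")], name="sample.fa.gz", compress=True),
            params,
        )
        assert np.array_equal(plain.hashes, gz.hashes)

    def test_multi_record_union(self, write_fasta):
        params = SketchParams(k=3, scale_factor=1.0)
        both = sketch_from_file(write_fasta([("a", "ACGTT"), ("b", "GGGCC")]), params)
        expected = set(stream_kmers("ACGTT", params)) | set(stream_kmers("GGGCC", params))
        assert len(both) == len(expected)

    def test_empty_file_warns(self, tmp_path):
        path = tmp_path / "empty.fa"
        path.write_text("")
        with pytest.warns(UserWarning, match="empty"):
            sk = sketch_from_file(path, SketchParams(k=3, scale_factor=1.0))
        assert len(sk) == 0

    def test_garbled_file_raises(self, tmp_path):
        path = tmp_path / "junk.txt"
        path.write_text("not a sequence file\n")
        with pytest.raises(SignatureFormatError):
            sketch_from_file(path, SketchParams(k=3, scale_factor=1.0))


class TestSignatures:
    def test_round_trip_identity(self, tmp_path):
        sk = int_sketch(range(200), scale_factor=0.8, name="sample-1", card=True)
        path = tmp_path / "s.sig"
        write_signature(sk, path)
        assert read_signature(path) == sk

    def test_hashes_stored_sorted_as_decimal_strings(self, tmp_path):
        sk = int_sketch(range(50), scale_factor=1.0)
        path = tmp_path / "s.sig"
        write_signature(sk, path)
        doc = json.loads(path.read_text())
        values = [int(v) for v in doc["hashes"]]
        assert all(isinstance(v, str) for v in doc["hashes"])
        assert values == sorted(values)

    def test_malformed_json(self, tmp_path):
        path = tmp_path / "bad.sig"
        path.write_text("{not json")
        with pytest.raises(SignatureFormatError, match="malformed"):
            read_signature(path)

    def test_missing_field_is_named(self, tmp_path):
        path = tmp_path / "missing.sig"
        path.write_text(json.dumps({"name": "x", "k": 3, "hashes": []}))
        with pytest.raises(SignatureFormatError, match="scale_factor"):
            read_signature(path)

    def test_out_of_range_parameter(self, tmp_path):
        path = tmp_path / "range.sig"
        path.write_text(
            json.dumps(
                {"name": "x", "k": 3, "scale_factor": 1.7, "hash_seed": 42, "hashes": []}
            )
        )
        with pytest.raises(SignatureFormatError, match="scale_factor"):
            read_signature(path)
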