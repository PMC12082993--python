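import gzip

import numpy as np
import pytest

from fracsketch import SketchParams, hash_u64_elements, sketch_from_hashes


@pytest.fixture
def write_fasta(tmp_path):
    def _write(records, name="sample.fa", compress=False):
        text = "".join(f">{rid}\n{seq}\n" for rid, seq in records)
        path = tmp_path / name
        if compress:
            with gzip.open(path, "wt") as fh:
                fh.write(text)
        else:
            path.write_text(text)
        return path

    return _write


@pytest.fixture
def write_fastq(tmp_path):
    def _write(records, name="sample.fq"):
        text = "".join(
            f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n" for rid, seq in records
        )
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write


def int_sketch(elements, scale_factor=1.0, k=21, hash_seed=42, name="", card=False):
    """Sketch of a set of integer elements via the real MurmurHash path."""
    elements = np.asarray(sorted(set(int(e) for e in elements)), dtype=np.uint64)
    params = SketchParams(k=k, scale_factor=scale_factor, hash_seed=hash_seed)
    return sketch_from_hashes(
        hash_u64_elements(elements, hash_seed),
        params,
        name=name,
        source_cardinality=len(elements) if card else None,
    )
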