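import numpy as np
import pytest

from chromstate.durations import NBDurationSpec
from chromstate.embedding import build_embedding
from chromstate.emissions import GeometricEmission


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_embedding():
    """4-substate embedding (r = 2, 2) with well-separated emissions."""
    return build_embedding(
        (NBDurationSpec(2, 0.05), NBDurationSpec(2, 0.1)),
        emissions=(GeometricEmission(0.02, 1, 50), GeometricEmission(0.67, 20, 10)),
    )


@pytest.fixture
def default_embedding():
    return build_embedding(
        (NBDurationSpec(5, 1e-4), NBDurationSpec(2, 1e-4)),
    )


SAM_HEADER = "@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:chr1\tLN:100000\n"


def make_sam(path, records):
    """Write a minimal coordinate-sorted SAM file.

    ``records`` are dicts with keys: pos (0-based), flag, isize, length
    (read length, default 50), pnext (0-based mate pos, default pos).
    """
    with open(path, "w") as fh:
        fh.write(SAM_HEADER)
        for i, rec in enumerate(sorted(records, key=lambda r: r["pos"])):
            length = rec.get("length", 50)
            pnext = rec.get("pnext", rec["pos"])
            fh.write(
                f"read{i}\t{rec['flag']}\tchr1\t{rec['pos'] + 1}\t60\t{length}M"
                f"\t=\t{pnext + 1}\t{rec.get('isize', 0)}"
                f"\t{'A' * length}\t{'I' * length}\n"
            )
    return path


@pytest.fixture
def sam_factory(tmp_path):
    def factory(records, name="toy.sam"):
        return str(make_sam(tmp_path / name, records))

    return factory
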