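import numpy as np
import pytest

from mutctx.formats_io import MutationRecord, ReferenceSet


@pytest.fixture
def rng():
    return np.random.default_rng(20140731)


@pytest.fixture
def small_ref():
    """A tiny deterministic reference with known cytosine contexts."""
    return ReferenceSet(
        sequences={
            "r1": "TGGCAACGTTCATT",
            "r2": "CCCTGGATCGAT",
        }
    )


@pytest.fixture
def random_ref(rng):
    bases = np.array(list("ACGT"))
    seq = "".join(bases[rng.integers(0, 4, size=5000)])
    return ReferenceSet(sequences={"chr1": seq})


def make_record(seq_name="chr1", pos=1, ref="C", alt="T", sample="s1"):
    return MutationRecord(sample_id=sample, seq_name=seq_name, pos=pos, ref=ref, alt=alt)
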