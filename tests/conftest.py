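import numpy as np
import pytest

from branchtrain import BranchSequence


def seq(labels, train_id="t", names=("L", "R")):
    """Shorthand: build a BranchSequence from 'LLRRL'-style strings."""
    if isinstance(labels, str):
        labels = [0 if c in "LlUu0" else 1 for c in labels]
    return BranchSequence(train_id, np.array(labels, dtype=np.int8), names)


@pytest.fixture
def make_seq():
    return seq
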