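import numpy as np
import pytest

from centrohor.decompose import Block


@pytest.fixture
def make_blocks():
    """Build a block list from raw sequences, tiled end to end."""

    def _make(seqs):
        blocks = []
        pos = 0
        for i, s in enumerate(seqs):
            blocks.append(Block(index=i, start=pos, end=pos + len(s), sequence=s))
            pos += len(s)
        return blocks

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
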