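from __future__ import annotations

import pytest

from gmycsampler import Alignment, UltrametricTree, figure1_fixture


@pytest.fixture(scope="session")
def fixture16():
    """The 16-tip / 8-group worked-example fixture and its imposed partition."""
    truth, imposed = figure1_fixture()
    return truth, imposed


@pytest.fixture
def three_tip_tree() -> UltrametricTree:
    return UltrametricTree.from_newick("((a:1,b:1):1,c:2);")


def make_alignment(n_records: int, length: int = 8, prefix: str = "s") -> Alignment:
    motif = "ACGTTGCA"
    seq = (motif * (length // len(motif) + 1))[:length]
    return Alignment(
        tuple((f"{prefix}{i:04d}", seq) for i in range(n_records))
    )


@pytest.fixture
def alignment500() -> Alignment:
    return make_alignment(500)
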