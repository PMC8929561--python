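import numpy as np
import pytest

from timenet import Timeline, TimelineRecord, build_network


def atom(res: int, name: str = "CA", resname: str = "GLY", chain: str = "A") -> str:
    return f"{chain}:{res}:{resname}:{name}"


@pytest.fixture
def triangle_network():
    """Three residues in a triangle; two coupled edges, one independent."""
    records = [
        TimelineRecord(atom(1), atom(2), "contact", Timeline([1, 1, 0, 0])),
        TimelineRecord(atom(2), atom(3), "contact", Timeline([1, 1, 0, 0])),
        TimelineRecord(atom(1), atom(3), "contact", Timeline([0, 1, 0, 1])),
    ]
    return build_network(records, 4)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
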