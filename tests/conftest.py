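import numpy as np
import pytest

from fractrl.netio import DirectedPattern


@pytest.fixture
def star3() -> DirectedPattern:
    """Hub 0 feeding two leaves: the worked 3-node example."""
    return DirectedPattern(3, {(0, 1), (0, 2)})


@pytest.fixture
def p3() -> DirectedPattern:
    """Directed chain 0 -> 1 -> 2."""
    return DirectedPattern(3, {(0, 1), (1, 2)})


@pytest.fixture
def ring100() -> DirectedPattern:
    arcs = set()
    for i in range(100):
        arcs.add((i, (i + 1) % 100))
        arcs.add(((i + 1) % 100, i))
    return DirectedPattern(100, arcs)


@pytest.fixture
def star_of_stars() -> DirectedPattern:
    """Hub -> 9 subhubs -> 10 leaves each (100 nodes), heavily heterogeneous."""
    arcs = set()
    nid = 1
    for _ in range(9):
        sh = nid
        nid += 1
        arcs |= {(0, sh), (sh, 0)}
        for _ in range(10):
            arcs |= {(sh, nid), (nid, sh)}
            nid += 1
    return DirectedPattern(nid, arcs)


def random_pattern(
    rng: np.random.Generator, n: int, density: float = 0.3, selfloops: bool = False
) -> DirectedPattern:
    arcs = set()
    for u in range(n):
        for v in range(n):
            if u == v and not selfloops:
                continue
            if rng.random() < density:
                arcs.add((u, v))
    return DirectedPattern(n, frozenset(arcs))
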