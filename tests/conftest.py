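import itertools

import pytest

import dctspace as d


@pytest.fixture(scope="session")
def rnni4():
    """RNNI move graph on 4 leaves (18 trees) with its vertex list."""
    graph = d.rnni_graph(4)
    return graph, list(graph.nodes)


@pytest.fixture(scope="session")
def dct34():
    """DCT_4 move graph on 3 leaves (18 trees) with its vertex list."""
    graph = d.dct_graph(3, 4)
    return graph, list(graph.nodes)


def all_caterpillars(n):
    """Every caterpillar ranked tree on n canonical leaves (n!/2 of them)."""
    labels = d.canonical_labels(n)
    seen = set()
    out = []
    for perm in itertools.permutations(labels):
        t = d.caterpillar_ranked(perm)
        if t not in seen:
            seen.add(t)
            out.append(t)
    return out
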