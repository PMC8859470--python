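import numpy as np
import pytest

from mpsnet import MPSNParams, assemble, build_template, InterLocalityGraph


@pytest.fixture
def fig_params():
    """The small reference instance: 12x12 lattice, 9 regions, K4 localities."""
    return MPSNParams(n=144, r=1, k=9, s=4, template_kind="complete", epsilon=1.0, rng_seed=7)


@pytest.fixture
def fig_graph(fig_params):
    return assemble(fig_params)


@pytest.fixture
def two_locality_pair():
    """Two s=4 localities joined by a single inter-locality edge (n=16, k=4)."""
    params = MPSNParams(n=16, r=1, k=4, s=4, epsilon=0.0, rng_seed=0)
    f_ld = InterLocalityGraph.from_edges(4, [(0, 1)])
    return params, f_ld


def brute_force_short_range(coords, r):
    """O(n^2) oracle for the short-range edge set."""
    edges = set()
    n = len(coords)
    for u in range(n):
        for v in range(u + 1, n):
            di = int(coords[u][0]) - int(coords[v][0])
            dj = int(coords[u][1]) - int(coords[v][1])
            if di * di + dj * dj <= r * r:
                edges.add((u, v))
    return edges
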