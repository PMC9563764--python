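import numpy as np
import pytest

from ctpathway.fixtures import FixtureSpec, make_network, make_pathways, make_profile
from ctpathway.gpcm import EdgeSource, InteractionEdge, build_gpcm


def edges(pairs, source=EdgeSource.pathway, origin=""):
    return [InteractionEdge(a, b, source, origin) for a, b in pairs]


@pytest.fixture
def two_node_gpcm():
    return build_gpcm(pathway_edges=edges([("A", "B")]))


@pytest.fixture
def path3_gpcm():
    # A - B - C
    return build_gpcm(pathway_edges=edges([("A", "B"), ("B", "C")]))


@pytest.fixture(scope="session")
def small_world():
    """300-gene network with 40 pathways and a background profile."""
    spec = FixtureSpec(n_genes=300, n_pathways=40, size_range=(6, 15), seed=11)
    gpcm = make_network(spec)
    pathways = make_pathways(gpcm, spec)
    profile = make_profile(gpcm, pathways, spec)
    return gpcm, pathways, profile, spec


def random_connected_gpcm(rng, n_max=200):
    """A random connected simple graph wrapped as a crosstalk map."""
    import networkx as nx

    n = int(rng.integers(10, n_max + 1))
    m = int(rng.integers(1, 5))
    g = nx.barabasi_albert_graph(n, min(m, n - 1), seed=int(rng.integers(2**31)))
    return build_gpcm(pathway_edges=edges([(f"N{a:04d}", f"N{b:04d}") for a, b in g.edges()]))
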