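import numpy as np
import pytest
from hypothesis import settings

from herbnet.network_model import Edge, NodeRef, TripartiteNetwork
from herbnet.protein_weighting import load_t2dm_table
from herbnet.traversal import PlantProteinProfile

settings.register_profile("det", derandomize=True, deadline=None)
settings.load_profile("det")


@pytest.fixture(scope="session")
def t2dm_table():
    return load_t2dm_table()


@pytest.fixture
def toy_profiles():
    """Three plants over two proteins with hand-computable scores.

    protein weights: p1=1.0, p2=0.5
    A={p1:0.9} -> total 0.9;  B={p2:1.0} -> total 0.5;  C={p1:0.5, p2:0.5} -> total 0.75
    pair scores: {A,B}=1.4, {A,C}=1.15, {B,C}=1.0
    """
    a = PlantProteinProfile("A", {"p1": ("G1", 1.0, 0.9)})
    b = PlantProteinProfile("B", {"p2": ("G2", 0.5, 1.0)})
    c = PlantProteinProfile("C", {"p1": ("G1", 1.0, 0.5), "p2": ("G2", 0.5, 0.5)})
    return [a, b, c]


def random_profiles(rng: np.random.Generator, n_plants: int, n_proteins: int):
    """Small random profile set for oracle comparisons."""
    weights = rng.uniform(0.1, 1.0, n_proteins)
    profiles = []
    for t in range(n_plants):
        prof = PlantProteinProfile(f"T{t:02d}")
        cov = rng.integers(1, n_proteins + 1)
        for i in rng.choice(n_proteins, size=cov, replace=False):
            prof.record(f"p{i}", f"G{i}", float(weights[i]), float(rng.uniform(0.05, 1.0)))
        profiles.append(prof)
    return profiles


def small_random_network(rng: np.random.Generator, n_nodes: int = 50, n_edges: int = 80):
    """Random mixed-kind network for reachability tests."""
    kinds = ["plant", "compound", "protein"]
    nets = ["A", "B", "C"]
    nodes = [
        NodeRef(kinds[i % 3], f"n{i}", nets[i % 3 if kinds[i % 3] != "plant" else 0])
        for i in range(n_nodes)
    ]
    net = TripartiteNetwork()
    for n in nodes:
        net.add_node(n)
    made = 0
    while made < n_edges:
        u, v = (nodes[int(i)] for i in rng.integers(0, n_nodes, 2))
        if u == v:
            continue
        net.add_edge(Edge(u, v, float(rng.uniform(0.1, 1.0)), "compound_similarity"))
        made += 1
    return net, nodes
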