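"""Shared fixtures and the independent reachability oracle.

The oracle computes the transitive closure by repeated boolean matrix
multiplication, independently of the package's per-source traversal, and
derives the hierarchy score by explicit pair counting.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from senet import LinkSpec, NodeSpec, SENetwork, nere_example_network


def closure_matrix(graph: nx.DiGraph) -> tuple[list, np.ndarray]:
    """Transitive closure by matrix powers: R = A | A^2 | ... | A^n."""
    nodes = list(graph.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    adjacency = np.zeros((n, n), dtype=bool)
    for u, v in graph.edges:
        adjacency[idx[u], idx[v]] = True
    reach = adjacency.copy()
    power = adjacency.copy()
    for _ in range(n):
        power = power @ adjacency
        reach |= power
    return nodes, reach


def hierarchy_bruteforce(graph: nx.DiGraph) -> float | None:
    """Hierarchy score from the matrix closure; None when no pair reachable."""
    nodes, reach = closure_matrix(graph)
    n_conn = n_sym = 0
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            if reach[i, j] or reach[j, i]:
                n_conn += 1
                if reach[i, j] and reach[j, i]:
                    n_sym += 1
    if n_conn == 0:
        return None
    return 1.0 - n_sym / n_conn


def random_digraph(n_nodes: int, n_arcs: int, seed: int) -> nx.DiGraph:
    """Simple random digraph without self-loops (nodes always present)."""
    rng = np.random.default_rng(seed)
    graph = nx.DiGraph()
    graph.add_nodes_from(f"n{i}" for i in range(n_nodes))
    pairs = [
        (f"n{i}", f"n{j}")
        for i in range(n_nodes)
        for j in range(n_nodes)
        if i != j
    ]
    k = min(n_arcs, len(pairs))
    for index in rng.choice(len(pairs), size=k, replace=False):
        graph.add_edge(*pairs[index])
    return graph


def tiny_network(links: list[tuple[str, str, str, str]],
                 nodes: dict[str, dict] | None = None) -> SENetwork:
    """Build a small network; node specs inferred unless overridden.

    ``links`` entries are (source, target, type, level); unseen node ids
    become social nodes present at every level.
    """
    ids = {l[0] for l in links} | {l[1] for l in links} | set(nodes or {})
    specs = []
    for nid in sorted(ids):
        kwargs = dict(
            id=nid, label=nid, category="social", gender="unspecified",
            group="none", role="", levels=frozenset({"land", "tree", "product"}),
        )
        kwargs.update((nodes or {}).get(nid, {}))
        specs.append(NodeSpec(**kwargs))
    return SENetwork(specs, [LinkSpec(*l) for l in links])


@pytest.fixture(scope="session")
def example_network() -> SENetwork:
    return nere_example_network()
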