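"""Cascades of rights and benefits: hierarchy, dominance, layers.

Two sub-networks are extracted from the full multilayer network, each on the
full node roster:

* the **cascade of rights** keeps ``Right`` and ``Action`` links -- how
  rights circulate amongst people and how people act on ecological elements;
* the **cascade of benefits** keeps ``Ecology``, ``Contribution`` and
  ``Transfer`` links -- how ecological elements interact, supply
  contributions to people, and how people pass these on.

Their hierarchical character is measured with the Krackhardt hierarchy
score: 1 minus the proportion of symmetrically reachable unordered pairs
among all reachable pairs; 1 for a fully hierarchical (acyclic-reachability)
graph and 0 when every reachable pair is mutual.  *Dominance* of a node is
the number of distinct other nodes it can reach along directed links; the
dominant actors sit at the top of the cascade.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .core import SUBSTANTIVE_TYPES, SENetwork, flatten

__all__ = [
    "PRESETS",
    "CascadeResult",
    "UndefinedScoreError",
    "reachability",
    "krackhardt_hierarchy",
    "dominance",
    "dominance_all",
    "assign_layers",
    "cascade",
    "compare_positions",
]

#: Named link-type selections for the two cascades and the full network.
PRESETS: Mapping[str, frozenset[str]] = {
    "rights": frozenset({"Right", "Action"}),
    "benefits": frozenset({"Ecology", "Contribution", "Transfer"}),
    "full": frozenset(SUBSTANTIVE_TYPES),
}


class UndefinedScoreError(Exception):
    """The hierarchy score is undefined (no reachable pair, i.e. no arcs)."""


def reachability(graph: nx.DiGraph) -> dict[str, set[str]]:
    """Map each node to the set of *other* nodes reachable along directed
    paths of length >= 1 (per-source traversal).

    The relation is over distinct ordered pairs: self-reachability is
    excluded by definition, matching the pair universe of the hierarchy
    score and of dominance.
    """
    return {node: set(nx.descendants(graph, node)) for node in graph.nodes}


def krackhardt_hierarchy(
    graph: nx.DiGraph,
    pair_universe: str = "reachable",
) -> float:
    """Krackhardt hierarchy score of a directed graph.

    Let R be the reachability relation (self-reachability excluded).  Over
    the unordered pairs {u, v} with u R v or v R u, the score is
    ``1 - (# pairs with both u R v and v R u) / (# pairs with at least one)``.
    Computed in exact rational arithmetic and returned as a float.

    Parameters
    ----------
    graph:
        Directed graph (isolated nodes allowed; they simply contribute no
        reachable pairs).
    pair_universe:
        ``"reachable"`` (default) restricts the denominator to pairs
        connected by reachability in at least one direction, so that
        retaining the full node roster in a sparse sub-network does not
        dilute the score.  ``"all"`` uses every unordered pair of distinct
        nodes, the convention of the original connectedness-corrected
        formulation.

    Raises
    ------
    UndefinedScoreError
        If no pair is reachable in either direction (arc-free graph).
    """
    if pair_universe not in ("reachable", "all"):
        raise ValueError(f"pair_universe must be 'reachable' or 'all', got {pair_universe!r}")
    reach = reachability(graph)
    nodes = list(graph.nodes)
    n_connected = 0
    n_symmetric = 0
    for i, u in enumerate(nodes):
        for v in nodes[i + 1 :]:
            uv = v in reach[u]
            vu = u in reach[v]
            if uv or vu:
                n_connected += 1
                if uv and vu:
                    n_symmetric += 1
    if n_connected == 0:
        raise UndefinedScoreError("no reachable pair: hierarchy score undefined")
    if pair_universe == "all":
        denominator = len(nodes) * (len(nodes) - 1) // 2
    else:
        denominator = n_connected
    return float(1 - Fraction(n_symmetric, denominator))


def dominance(graph: nx.DiGraph, node_id: str) -> int:
    """Number of distinct other nodes reachable from ``node_id``."""
    if node_id not in graph:
        raise KeyError(f"unknown node id {node_id!r}")
    return len(nx.descendants(graph, node_id) - {node_id})


def dominance_all(graph: nx.DiGraph) -> dict[str, int]:
    """Dominance of every node."""
    return {node: len(nx.descendants(graph, node) - {node}) for node in graph.nodes}


def assign_layers(graph: nx.DiGraph, dom: Mapping[str, int] | None = None) -> dict[str, int]:
    """Depth of each node below the dominant top (0 = most dominant).

    Depth is the longest directed path from any maximal-dominance node,
    computed on the condensation of the graph (strongly connected components
    collapsed), which is acyclic, so the longest path is well defined.
    Components unreachable from every top node (secondary hierarchies,
    isolated nodes) start at depth 1 and deepen along their own arcs, so
    that exactly the maximal-dominance nodes occupy layer 0.
    """
    if dom is None:
        dom = dominance_all(graph)
    if not graph.nodes:
        return {}
    top_value = max(dom.values())
    cond = nx.condensation(graph)
    membership = cond.graph["mapping"]  # node -> component index

    # a maximal-dominance component has no predecessor (a predecessor would
    # reach strictly more nodes), so depth 0 is consistent with the DP below
    top_components = {membership[n] for n in graph.nodes if dom[n] == top_value}
    depth: dict[int, int] = {}
    for c in nx.topological_sort(cond):
        if c in top_components:
            depth[c] = 0
        else:
            preds = [depth[p] for p in cond.predecessors(c)]
            depth[c] = (max(preds) + 1) if preds else 1

    return {node: depth[membership[node]] for node in graph.nodes}


@dataclass
class CascadeResult:
    """A cascade sub-network with its hierarchy score, dominance and layers.

    ``hierarchy`` is ``None`` when the selection yields an arc-free graph
    (undefined score marker).  ``layers`` maps node id to a non-negative
    depth; the maximal-dominance nodes sit at depth 0.
    """

    selection: frozenset[str]
    graph: nx.DiGraph
    hierarchy: float | None
    dominance: dict[str, int]
    layers: dict[str, int]
    pair_universe: str = "reachable"

    @property
    def hierarchy_defined(self) -> bool:
        return self.hierarchy is not None

    def ranking(self, social_only: bool = False) -> pd.DataFrame:
        """Nodes ranked by dominance (rank 1 = most dominant).

        Ties are broken by node id, lexicographically, for deterministic
        output.
        """
        ids = [
            n
            for n in self.graph.nodes
            if not social_only or self.graph.nodes[n]["category"] == "social"
        ]
        ordered = sorted(ids, key=lambda n: (-self.dominance[n], n))
        frame = pd.DataFrame(
            {
                "node": ordered,
                "dominance": [self.dominance[n] for n in ordered],
                "layer": [self.layers[n] for n in ordered],
            }
        )
        frame["rank"] = range(1, len(ordered) + 1)
        return frame.set_index("node")


def cascade(
    network: SENetwork,
    selection: str | Iterable[str],
    pair_universe: str = "reachable",
) -> CascadeResult:
    """Extract a cascade sub-network and score it.

    ``selection`` is a preset name (``"rights"``, ``"benefits"``, ``"full"``)
    or an explicit non-empty set of link types.  The flattened graph keeps
    the full node roster; hierarchy, per-node dominance and layer depths are
    computed on it.
    """
    if isinstance(selection, str):
        try:
            types = PRESETS[selection]
        except KeyError:
            raise ValueError(
                f"unknown preset {selection!r}; expected one of {sorted(PRESETS)}"
            ) from None
    else:
        types = frozenset(selection)
        if not types:
            raise ValueError("empty link-type selection")
    graph = flatten(network, levels=None, types=types)
    try:
        score: float | None = krackhardt_hierarchy(graph, pair_universe=pair_universe)
    except UndefinedScoreError:
        score = None
    dom = dominance_all(graph)
    return CascadeResult(
        selection=types,
        graph=graph,
        hierarchy=score,
        dominance=dom,
        layers=assign_layers(graph, dom),
        pair_universe=pair_universe,
    )


def compare_positions(
    a: CascadeResult, b: CascadeResult, social_only: bool = True
) -> pd.DataFrame:
    """Dominance ranks of each node in two cascades, side by side.

    With ``social_only`` (default) the comparison is restricted to social
    nodes: in the rights cascade the ecological elements are necessarily at
    the bottom and in the benefits cascade at the top, so only the social
    positions are informative.  Raises ``ValueError`` on roster mismatch.
    """
    if set(a.graph.nodes) != set(b.graph.nodes):
        raise ValueError("cascades compare only over an identical node roster")
    rank_a = a.ranking(social_only=social_only)
    rank_b = b.ranking(social_only=social_only)
    table = pd.DataFrame(
        {
            "dominance_a": rank_a["dominance"],
            "rank_a": rank_a["rank"],
            "dominance_b": rank_b["dominance"],
            "rank_b": rank_b["rank"],
        }
    )
    return table.sort_values(["rank_a", "rank_b"])
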