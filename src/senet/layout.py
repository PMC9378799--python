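"""Coordinates for drawing the network and its cascades.

Two regimes: a force-directed (Fruchterman-Reingold) layout of the full
network with node areas scaled by degree, and a top-down layered drawing of
a cascade in which the most dominant actors sit at the top and node size is
proportional to dominance.  Crossing reduction in the layered drawing uses
two barycenter sweeps (one down, one up) -- exact crossing minimisation is
NP-hard and the drawing is presentational.

Coordinates are the tested artifact; rendering to SVG/PNG is a thin
optional layer on matplotlib.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import networkx as nx
import pandas as pd

from .cascades import CascadeResult

__all__ = ["LayoutResult", "force_layout", "hierarchical_layout", "render"]


@dataclass
class LayoutResult:
    """Node coordinates (abstract units) and drawing weights."""

    coords: dict[str, tuple[float, float]]
    sizes: dict[str, float]
    mode: str

    def to_frame(self) -> pd.DataFrame:
        """Coordinates as a DataFrame with columns x, y, size."""
        frame = pd.DataFrame(
            {
                "id": list(self.coords),
                "x": [self.coords[n][0] for n in self.coords],
                "y": [self.coords[n][1] for n in self.coords],
                "size": [self.sizes[n] for n in self.coords],
            }
        )
        return frame.set_index("id")

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)


def force_layout(
    graph: nx.DiGraph, iterations: int = 50, seed: int = 0
) -> LayoutResult:
    """Force-directed layout: linked nodes attract, all pairs repel.

    Deterministic for a fixed seed; node sizes are proportional to the
    all-degree in ``graph``.  A single node is placed at the origin.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    pos = nx.spring_layout(graph, iterations=iterations, seed=seed)
    coords = {n: (float(x), float(y)) for n, (x, y) in pos.items()}
    sizes = {n: float(d) for n, d in graph.degree()}
    return LayoutResult(coords=coords, sizes=sizes, mode="force")


def _barycenter_order(
    layer_nodes: list[str],
    x_ref: Mapping[str, float],
    neighbours: Mapping[str, list[str]],
) -> list[str]:
    """Reorder one layer by the mean x of each node's reference-layer
    neighbours; nodes without neighbours keep their current position value."""
    current = {n: i for i, n in enumerate(layer_nodes)}

    def key(n: str) -> tuple[float, str]:
        ref = [x_ref[m] for m in neighbours.get(n, []) if m in x_ref]
        return ((sum(ref) / len(ref)) if ref else float(current[n]), n)

    return sorted(layer_nodes, key=key)


def hierarchical_layout(result: CascadeResult) -> LayoutResult:
    """Top-down layered drawing of a cascade.

    y = -depth (layer 0, the dominant nodes, on top).  Within each layer the
    horizontal order starts from sorted node ids and is refined by one
    downward and one upward barycenter pass over the neighbours in the
    adjacent layer; x positions are centred around zero.  Sizes are
    proportional to dominance.
    """
    graph = result.graph
    layers: dict[int, list[str]] = {}
    for node, depth in result.layers.items():
        layers.setdefault(depth, []).append(node)
    depths = sorted(layers)
    order = {d: sorted(layers[d]) for d in depths}

    # neighbours regardless of arc direction (arcs may point either way
    # between adjacent layers once cycles are condensed)
    adj: dict[str, list[str]] = {n: [] for n in graph.nodes}
    for u, v in graph.edges:
        adj[u].append(v)
        adj[v].append(u)

    def xs(nodes: list[str]) -> dict[str, float]:
        k = len(nodes)
        return {n: i - (k - 1) / 2.0 for i, n in enumerate(nodes)}

    # downward pass: order each layer by barycenters in the layer above
    for upper, lower in zip(depths, depths[1:]):
        ref = xs(order[upper])
        in_upper = set(order[upper])
        nbrs = {n: [m for m in adj[n] if m in in_upper] for n in order[lower]}
        order[lower] = _barycenter_order(order[lower], ref, nbrs)
    # upward pass: refine each layer by barycenters in the layer below
    for lower, upper in zip(reversed(depths), list(reversed(depths))[1:]):
        ref = xs(order[lower])
        in_lower = set(order[lower])
        nbrs = {n: [m for m in adj[n] if m in in_lower] for n in order[upper]}
        order[upper] = _barycenter_order(order[upper], ref, nbrs)

    coords: dict[str, tuple[float, float]] = {}
    for d in depths:
        for n, x in xs(order[d]).items():
            coords[n] = (x, -float(d))
    sizes = {n: float(result.dominance[n]) for n in graph.nodes}
    return LayoutResult(coords=coords, sizes=sizes, mode="hierarchy")


def render(
    graph: nx.DiGraph,
    layout: LayoutResult,
    path: str | Path,
    *,
    base_size: float = 60.0,
    label: bool = True,
) -> None:
    """Render a laid-out graph to SVG/PNG (extension decides the format)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 6))
    max_size = max(layout.sizes.values()) if layout.sizes else 1.0
    node_sizes = [
        base_size * (0.2 + (layout.sizes[n] / max_size if max_size else 0.0))
        for n in graph.nodes
    ]
    colors = [
        "#2a7f3f" if graph.nodes[n].get("category") == "ecological" else "#4169a8"
        for n in graph.nodes
    ]
    pos = {n: layout.coords[n] for n in graph.nodes}
    nx.draw_networkx_edges(graph, pos, ax=ax, arrowsize=8, alpha=0.5, width=0.8)
    nx.draw_networkx_nodes(graph, pos, ax=ax, node_size=node_sizes, node_color=colors)
    if label:
        nx.draw_networkx_labels(graph, pos, ax=ax, font_size=6)
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(str(path))
    plt.close(fig)
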