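"""Descriptive indicators of the multilayer network.

Per-level summaries (node count, link count, density, reciprocity, gender
composition), node degrees, and the dyad census -- the inventory of link-type
combinations observed between connected pairs of nodes.

Two representations coexist deliberately: densities use the pair-collapsed
arc count (the denominator counts ordered node pairs), while ``n_links`` and
degrees count raw substantive links, parallel links included.  Vertical
Coupling records are excluded everywhere.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping

from .core import LEVELS, SENetwork, _canon

__all__ = [
    "LevelSummary",
    "DyadProfile",
    "degree",
    "level_summary",
    "gender_composition",
    "dyad_census",
    "census_by_profile",
]


@dataclass(frozen=True)
class LevelSummary:
    """Indicators for one interaction level.

    ``density`` is the number of distinct directed arcs divided by
    n*(n-1), the number of possible directed arcs; ``None`` when fewer
    than two nodes belong to the level (undefined, not zero).
    ``reciprocity`` is the share of links whose reverse link exists at the
    same level, regardless of type (a Transfer answered by a Payment is a
    reciprocated exchange).
    """

    level: str
    n_nodes: int
    n_links: int
    density: float | None
    reciprocity: float | None
    gender_share: Mapping[str, float]


@dataclass(frozen=True)
class DyadProfile:
    """The combination of link types observed between one connected pair.

    ``profile`` is a direction-symmetric canonical tuple of
    ``(direction, type)`` entries, ``direction`` being ``">"`` (along the
    canonical orientation of the pair) or ``"<"`` (against it); the pair
    {u, v} yields the same profile as {v, u}.  ``profile_count`` is the
    number of connected pairs in the network sharing this profile.
    """

    pair: tuple[str, str]
    profile: tuple[tuple[str, str], ...]
    reciprocal: bool
    profile_count: int


def degree(network: SENetwork, node_id: str, direction: str = "all") -> int:
    """Number of substantive links from/to a node (parallel links counted).

    ``direction`` is ``"in"``, ``"out"`` or ``"all"`` (= in + out).
    """
    if node_id not in network.nodes:
        raise KeyError(f"unknown node id {node_id!r}")
    if direction not in ("in", "out", "all"):
        raise ValueError(f"direction must be in/out/all, got {direction!r}")
    n_in = n_out = 0
    for link in network.substantive_links:
        if link.target == node_id:
            n_in += 1
        if link.source == node_id:
            n_out += 1
    if direction == "in":
        return n_in
    if direction == "out":
        return n_out
    return n_in + n_out


def gender_composition(network: SENetwork, level: str) -> dict[str, float]:
    """Gender fractions among gendered social nodes at a level.

    Nodes with unspecified gender are excluded from the denominator; the
    mapping is empty when no gendered node belongs to the level.
    """
    level = _canon(level, LEVELS, "level")
    counts = Counter(
        n.gender
        for n in network.nodes.values()
        if level in n.levels and n.gender != "unspecified"
    )
    total = sum(counts.values())
    if total == 0:
        return {}
    return {g: c / total for g, c in sorted(counts.items())}


def level_summary(network: SENetwork, level: str) -> LevelSummary:
    """Node count, link count, density, reciprocity and gender mix at a level."""
    level = _canon(level, LEVELS, "level")
    n_nodes = len(network.node_ids_at(level))
    links = network.links_at(level)
    arcs = {(l.source, l.target) for l in links}

    density: float | None
    if n_nodes >= 2:
        density = len(arcs) / (n_nodes * (n_nodes - 1))
    else:
        density = None

    reciprocity: float | None
    if links:
        n_recip = sum(1 for l in links if (l.target, l.source) in arcs)
        reciprocity = n_recip / len(links)
    else:
        reciprocity = None

    return LevelSummary(
        level=level,
        n_nodes=n_nodes,
        n_links=len(links),
        density=density,
        reciprocity=reciprocity,
        gender_share=gender_composition(network, level),
    )


def _canonical_profile(
    u: str, v: str, links_uv: list[str], links_vu: list[str]
) -> tuple[tuple[str, str], ...]:
    """Direction-symmetric profile of a pair: of the two orientations' sorted
    (direction, type) tuples, the one whose forward entries lead."""

    def orient(fwd: list[str], bwd: list[str]) -> tuple[tuple[str, str], ...]:
        return tuple(sorted(
            {(">", t) for t in fwd} | {("<", t) for t in bwd},
            key=lambda dt: (dt[0] != ">", dt[1]),
        ))

    as_uv, as_vu = orient(links_uv, links_vu), orient(links_vu, links_uv)
    key = lambda prof: tuple((d != ">", t) for d, t in prof)
    return min(as_uv, as_vu, key=key)


def dyad_census(network: SENetwork) -> list[DyadProfile]:
    """One :class:`DyadProfile` per connected unordered pair of nodes.

    All levels are pooled; a pair is reciprocal iff it has at least one link
    in each direction.  Profile counts over the returned list sum to the
    number of connected pairs.
    """
    by_pair: dict[tuple[str, str], tuple[list[str], list[str]]] = {}
    for link in network.substantive_links:
        u, v = sorted((link.source, link.target))
        fwd, bwd = by_pair.setdefault((u, v), ([], []))
        (fwd if link.source == u else bwd).append(link.type)

    profiles = {
        pair: _canonical_profile(pair[0], pair[1], fwd, bwd)
        for pair, (fwd, bwd) in by_pair.items()
    }
    profile_counts = Counter(profiles.values())
    return [
        DyadProfile(
            pair=pair,
            profile=profiles[pair],
            reciprocal=bool(fwd and bwd),
            profile_count=profile_counts[profiles[pair]],
        )
        for pair, (fwd, bwd) in sorted(by_pair.items())
    ]


def census_by_profile(network: SENetwork) -> list[tuple[tuple[tuple[str, str], ...], int]]:
    """Aggregated census: (profile, occurrence count), most frequent first."""
    counts = Counter(d.profile for d in dyad_census(network))
    return sorted(counts.items(), key=lambda item: (-item[1], item[0]))
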