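"""Domain types and construction of the multilayer social-ecological network.

A social-ecological network (SEN) couples social actors (farmers, spouses,
traders, ...) and ecological elements (land, animals, trees, seeds) in one
directed network.  Interactions happen at three nested levels -- the *land*,
the *tree*, and the harvested *product* -- and each directed link carries one
of seven substantive types (rights, actions, ecological flows, contributions,
transfers, payments, work).  A node that participates at several levels is
represented once, with a set of level memberships; a *Coupling* record ties
the node to itself across levels and is retained for provenance but excluded
from every graph metric.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

__all__ = [
    "LEVELS",
    "LINK_TYPES",
    "SUBSTANTIVE_TYPES",
    "GENDERS",
    "GROUPS",
    "CATEGORIES",
    "ENDPOINT_RULES",
    "NodeSpec",
    "LinkSpec",
    "SENetwork",
    "ValidationReport",
    "SenetError",
    "FormatError",
    "NetworkValidationError",
    "load_network",
    "write_network",
    "validate",
    "flatten",
    "to_graphml",
]

#: Interaction levels, in their vertical order (land at the bottom of the
#: landscape, product at the end of the harvest chain).
LEVELS: tuple[str, ...] = ("land", "tree", "product")

#: The seven substantive link types plus the vertical Coupling record.
SUBSTANTIVE_TYPES: tuple[str, ...] = (
    "Right",
    "Action",
    "Ecology",
    "Contribution",
    "Transfer",
    "Payment",
    "Work",
)
LINK_TYPES: tuple[str, ...] = SUBSTANTIVE_TYPES + ("Coupling",)

CATEGORIES: tuple[str, ...] = ("social", "ecological")
GENDERS: tuple[str, ...] = ("male", "female", "unspecified")
GROUPS: tuple[str, ...] = (
    "native_farmer",
    "migrant_farmer",
    "pastoralist",
    "external",
    "none",
)

#: Expected (source category, target category) per link type.  Violations are
#: reported as warnings, not errors: field data pair e.g. "work" with
#: "contribution" between two social actors (labour paid in kind), so the
#: taxonomy is advisory at the endpoints.
ENDPOINT_RULES: Mapping[str, tuple[str, str]] = {
    "Right": ("social", "social"),
    "Transfer": ("social", "social"),
    "Payment": ("social", "social"),
    "Work": ("social", "social"),
    "Action": ("social", "ecological"),
    "Ecology": ("ecological", "ecological"),
    "Contribution": ("ecological", "social"),
}


class SenetError(Exception):
    """Base class for senet errors."""


class FormatError(SenetError):
    """A tabular input file is malformed (missing column, unknown vocabulary)."""


class NetworkValidationError(SenetError):
    """A network violates a hard structural invariant."""


def _canon(value: str, vocab: Sequence[str], what: str) -> str:
    """Normalize ``value`` case-insensitively against a controlled vocabulary."""
    v = str(value).strip()
    for item in vocab:
        if v.lower() == item.lower():
            return item
    raise FormatError(f"unknown {what} {value!r}; expected one of {list(vocab)}")


@dataclass(frozen=True)
class NodeSpec:
    """One actor or ecological element of the network.

    Parameters
    ----------
    id:
        Short unique token (e.g. ``"native_farmer_man"``).
    label:
        Free-text display name.
    category:
        ``"social"`` or ``"ecological"``.
    gender:
        ``"male"``, ``"female"`` or ``"unspecified"``; ecological nodes are
        always ``"unspecified"``.
    group:
        Ethnic/role group: ``native_farmer``, ``migrant_farmer``,
        ``pastoralist``, ``external`` (traders, consumers, visitors) or
        ``none`` (ecological elements).
    role:
        Free-text role tag (``first_spouse``, ``chief``, ``tree`` ...).
    levels:
        Non-empty subset of :data:`LEVELS` at which the node interacts.
    """

    id: str
    label: str = ""
    category: str = "social"
    gender: str = "unspecified"
    group: str = "none"
    role: str = ""
    levels: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "category", _canon(self.category, CATEGORIES, "category"))
        object.__setattr__(self, "gender", _canon(self.gender, GENDERS, "gender"))
        object.__setattr__(self, "group", _canon(self.group, GROUPS, "group"))
        levels = frozenset(_canon(l, LEVELS, "level") for l in self.levels)
        object.__setattr__(self, "levels", levels)


@dataclass(frozen=True)
class LinkSpec:
    """One directed typed link, at a level (or ``"vertical"`` for Coupling)."""

    source: str
    target: str
    type: str
    level: str
    note: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "type", _canon(self.type, LINK_TYPES, "link type"))
        object.__setattr__(
            self, "level", _canon(self.level, LEVELS + ("vertical",), "link level")
        )

    @property
    def is_coupling(self) -> bool:
        return self.type == "Coupling"


@dataclass
class ValidationReport:
    """Outcome of :func:`validate`: hard-invariant violations and advisories."""

    errors: list[tuple[str, str, str]] = field(default_factory=list)
    warnings: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


class SENetwork:
    """A validated multilayer directed social-ecological network.

    The container is permissive on construction (so that a broken network can
    be inspected via :func:`validate`); :func:`load_network` refuses files
    whose hard invariants fail.
    """

    def __init__(self, nodes: Iterable[NodeSpec], links: Iterable[LinkSpec]):
        self.nodes: dict[str, NodeSpec] = {}
        for node in nodes:
            if node.id in self.nodes:
                raise NetworkValidationError(f"duplicate node id {node.id!r}")
            self.nodes[node.id] = node
        self.links: list[LinkSpec] = list(links)
        self.levels: tuple[str, ...] = LEVELS

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"SENetwork(n_nodes={len(self.nodes)}, n_links={len(self.links)})"

    def node_ids_at(self, level: str) -> list[str]:
        """Ids of nodes whose memberships include ``level`` (roster order)."""
        level = _canon(level, LEVELS, "level")
        return [n.id for n in self.nodes.values() if level in n.levels]

    def links_at(self, level: str, include_coupling: bool = False) -> list[LinkSpec]:
        """Links at ``level``; Coupling records excluded unless requested."""
        level = _canon(level, LEVELS + ("vertical",), "level")
        return [
            l
            for l in self.links
            if l.level == level and (include_coupling or not l.is_coupling)
        ]

    @property
    def substantive_links(self) -> list[LinkSpec]:
        """All links except vertical Coupling records."""
        return [l for l in self.links if not l.is_coupling]


# ---------------------------------------------------------------------------
# validation

def validate(network: SENetwork) -> ValidationReport:
    """Check every structural invariant; return a deterministic report.

    Hard invariants (errors): endpoints exist; link level lies within both
    endpoints' level memberships; no duplicate (source, target, type, level)
    tuple; Coupling links are self-links and the only links at the
    ``vertical`` level; node levels non-empty; ecological nodes ungendered.
    Endpoint-category mismatches against :data:`ENDPOINT_RULES` are warnings.
    """
    report = ValidationReport()
    for node in network.nodes.values():
        if not node.levels:
            report.errors.append(
                ("node-levels-nonempty", node.id, "node has no level membership")
            )
        if node.category == "ecological" and node.gender != "unspecified":
            report.errors.append(
                ("ecological-ungendered", node.id, "ecological node carries a gender")
            )

    seen: set[tuple[str, str, str, str]] = set()
    for link in network.links:
        where = f"{link.source}->{link.target} {link.type}@{link.level}"
        key = (link.source, link.target, link.type, link.level)
        if key in seen:
            report.errors.append(("no-duplicate-links", where, "duplicate link tuple"))
        seen.add(key)

        src = network.nodes.get(link.source)
        tgt = network.nodes.get(link.target)
        if src is None:
            report.errors.append(
                ("endpoint-exists", where, f"unknown source node {link.source!r}")
            )
        if tgt is None:
            report.errors.append(
                ("endpoint-exists", where, f"unknown target node {link.target!r}")
            )

        if link.is_coupling:
            if link.source != link.target:
                report.errors.append(
                    (
                        "coupling-self",
                        where,
                        "Coupling links tie the same node to itself across levels",
                    )
                )
            if link.level != "vertical":
                report.errors.append(
                    ("coupling-vertical", where, "Coupling links must be vertical")
                )
        else:
            if link.level == "vertical":
                report.errors.append(
                    ("coupling-vertical", where, "only Coupling links may be vertical")
                )
            elif src is not None and tgt is not None:
                if link.level not in src.levels or link.level not in tgt.levels:
                    report.errors.append(
                        (
                            "link-level-membership",
                            where,
                            "link level outside an endpoint's level memberships",
                        )
                    )
            if link.source == link.target:
                report.errors.append(
                    ("no-self-links", where, "self-links are reserved for Coupling")
                )
            rule = ENDPOINT_RULES.get(link.type)
            if rule is not None and src is not None and tgt is not None:
                if (src.category, tgt.category) != rule:
                    report.warnings.append(
                        (
                            "endpoint-category",
                            where,
                            f"{link.type} links are expected "
                            f"{rule[0]} -> {rule[1]}, found "
                            f"{src.category} -> {tgt.category}",
                        )
                    )
    return report


# ---------------------------------------------------------------------------
# tabular IO  (UTF-8 CSV with a header row; levels joined by "|")

NODE_COLUMNS = ("id", "label", "category", "gender", "group", "role", "levels")
LINK_COLUMNS = ("source", "target", "type", "level", "note")


def _read_rows(path: str | Path, required: Sequence[str]) -> list[dict[str, str]]:
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in required:
            if col not in header:
                raise FormatError(f"{path.name}: missing required column {col!r}")
        return [row for row in reader if any((v or "").strip() for v in row.values())]


def load_network(nodes_table: str | Path, links_table: str | Path) -> SENetwork:
    """Read a network from a nodes CSV and a links CSV.

    Raises :class:`FormatError` on malformed files and
    :class:`NetworkValidationError` when the data violate a hard invariant
    (e.g. a link referencing an absent node id).
    """
    node_rows = _read_rows(nodes_table, NODE_COLUMNS)
    link_rows = _read_rows(links_table, LINK_COLUMNS)

    nodes = [
        NodeSpec(
            id=row["id"].strip(),
            label=(row.get("label") or "").strip(),
            category=row["category"],
            gender=row.get("gender") or "unspecified",
            group=row.get("group") or "none",
            role=(row.get("role") or "").strip(),
            levels=frozenset(
                part for part in (row.get("levels") or "").split("|") if part.strip()
            ),
        )
        for row in node_rows
    ]
    links = [
        LinkSpec(
            source=row["source"].strip(),
            target=row["target"].strip(),
            type=row["type"],
            level=row["level"],
            note=(row.get("note") or "").strip(),
        )
        for row in link_rows
    ]
    network = SENetwork(nodes, links)
    report = validate(network)
    if not report.ok:
        first = report.errors[0]
        raise NetworkValidationError(
            f"{len(report.errors)} validation error(s); first: "
            f"[{first[0]}] {first[1]}: {first[2]}"
        )
    return network


def write_network(
    network: SENetwork, nodes_table: str | Path, links_table: str | Path
) -> None:
    """Write the node and link tables back to CSV (round-trips with load)."""
    with Path(nodes_table).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(NODE_COLUMNS)
        for node in network.nodes.values():
            writer.writerow(
                [
                    node.id,
                    node.label,
                    node.category,
                    node.gender,
                    node.group,
                    node.role,
                    "|".join(l for l in LEVELS if l in node.levels),
                ]
            )
    with Path(links_table).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(LINK_COLUMNS)
        for link in network.links:
            writer.writerow([link.source, link.target, link.type, link.level, link.note])


# ---------------------------------------------------------------------------
# flattening and export

def _normalize_selection(
    values: Iterable[str] | None, vocab: Sequence[str], what: str
) -> frozenset[str]:
    if values is None:
        return frozenset(vocab)
    selected = frozenset(_canon(v, vocab, what) for v in values)
    if not selected:
        raise ValueError(f"empty {what} selection")
    return selected


def flatten(
    network: SENetwork,
    levels: Iterable[str] | None = None,
    types: Iterable[str] | None = None,
) -> nx.DiGraph:
    """Collapse selected links into a simple directed graph on the full roster.

    An arc (u, v) exists iff at least one substantive link of a selected type
    at a selected level runs u -> v; parallel links collapse onto one arc
    (their types are kept on the arc's ``types`` attribute).  Coupling records
    and self-loops are dropped.  Every node appears, connected or not, so that
    cascade sub-networks keep the full roster.
    """
    sel_levels = _normalize_selection(levels, LEVELS, "level")
    sel_types = _normalize_selection(types, SUBSTANTIVE_TYPES, "link type")

    graph = nx.DiGraph()
    for node in network.nodes.values():
        graph.add_node(
            node.id,
            label=node.label,
            category=node.category,
            gender=node.gender,
            group=node.group,
            role=node.role,
            levels="|".join(l for l in LEVELS if l in node.levels),
        )
    for link in network.links:
        if link.is_coupling or link.source == link.target:
            continue
        if link.level in sel_levels and link.type in sel_types:
            if graph.has_edge(link.source, link.target):
                types_seen = set(graph[link.source][link.target]["types"].split("|"))
                types_seen.add(link.type)
                graph[link.source][link.target]["types"] = "|".join(sorted(types_seen))
                graph[link.source][link.target]["n_links"] += 1
            else:
                graph.add_edge(link.source, link.target, types=link.type, n_links=1)
    return graph


def to_graphml(obj: SENetwork | nx.DiGraph, path: str | Path) -> None:
    """Export a network (all links, typed) or a flattened graph to GraphML."""
    if isinstance(obj, SENetwork):
        graph = nx.MultiDiGraph()
        for node in obj.nodes.values():
            graph.add_node(
                node.id,
                label=node.label,
                category=node.category,
                gender=node.gender,
                group=node.group,
                role=node.role,
                levels="|".join(l for l in LEVELS if l in node.levels),
            )
        for link in obj.links:
            graph.add_edge(
                link.source, link.target, type=link.type, level=link.level, note=link.note
            )
    else:
        graph = obj
    nx.write_graphml(graph, str(path))
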