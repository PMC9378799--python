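"""Synthetic social-ecological networks for testing and demonstration.

Two generators:

* :func:`nere_roster` / :func:`nere_example_network` -- a fixed, hand-curated
  roster and link set *stylized after* the published account of the nere
  (*Parkia biglobosa*) agroforestry system: five ecological nodes, social
  actors differentiated by gender, ethnic/role group and spouse status,
  10/11/16 nodes at the land/tree/product levels, a fully hierarchical
  rights cascade topped by the native farmer man, and a benefits cascade
  with exactly one reciprocated reachable pair and women as the dominant
  social nodes.  It is a synthetic illustration, not a
  coded field dataset.
* :func:`generate` -- seeded random networks with tunable per-level density,
  reciprocity and link-type mix, whose ``Right``/``Action`` arcs follow a
  latent dominance order so that reciprocity 0 yields an acyclic rights
  layer by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import (
    LEVELS,
    SUBSTANTIVE_TYPES,
    LinkSpec,
    NodeSpec,
    SENetwork,
)

__all__ = ["GenConfig", "nere_roster", "nere_example_network", "generate"]


def _node(id, label, category, gender, group, role, levels):
    return NodeSpec(
        id=id,
        label=label,
        category=category,
        gender=gender,
        group=group,
        role=role,
        levels=frozenset(levels),
    )


def nere_roster() -> list[NodeSpec]:
    """The fixed stylized roster: 16 social actors and 5 ecological elements.

    Level memberships give 10 land-level, 11 tree-level and 16 product-level
    nodes.  Narrative constraints are honoured: pastoralist men interact only
    at the land level, pastoralist women at the tree and product levels, and
    the external actors (trader, consumer, visitor, person in hardship)
    appear where the products circulate.
    """
    eco = "ecological"
    soc = "social"
    return [
        # ecological elements
        _node("land", "Land", eco, "unspecified", "none", "land", {"land"}),
        _node("animals", "Animals", eco, "unspecified", "none", "animals", {"land"}),
        _node("nere_tree", "Nere tree", eco, "unspecified", "none", "tree", {"land", "tree"}),
        _node("seeds_on_tree", "Seeds on tree", eco, "unspecified", "none", "seeds_on_tree", {"tree"}),
        _node("harvested_seeds", "Harvested seeds", eco, "unspecified", "none", "harvested_seeds", {"product"}),
        # native farmer household
        _node("native_farmer_man", "Native farmer man", soc, "male", "native_farmer", "household_head", {"land", "tree", "product"}),
        _node("native_woman_first", "Native woman, first spouse", soc, "female", "native_farmer", "first_spouse", {"land", "tree", "product"}),
        _node("native_woman_other", "Native woman, other spouse", soc, "female", "native_farmer", "other_spouse", {"tree", "product"}),
        _node("chief", "Traditional chief", soc, "male", "native_farmer", "chief", {"land", "tree", "product"}),
        _node("helper_woman", "Helping woman of the lineage", soc, "female", "native_farmer", "helper", {"product"}),
        # migrant farmer household
        _node("migrant_farmer_man", "Migrant farmer man", soc, "male", "migrant_farmer", "household_head", {"land", "tree", "product"}),
        _node("migrant_woman_first", "Migrant woman, first spouse", soc, "female", "migrant_farmer", "first_spouse", {"land", "tree", "product"}),
        _node("migrant_woman_other", "Migrant woman, other spouse", soc, "female", "migrant_farmer", "other_spouse", {"tree", "product"}),
        _node("migrant_youth", "Migrant youth", soc, "unspecified", "migrant_farmer", "youth", {"land", "tree", "product"}),
        # pastoralists
        _node("pastoralist_man", "Pastoralist man", soc, "male", "pastoralist", "herder", {"land"}),
        _node("pastoralist_woman", "Pastoralist woman", soc, "female", "pastoralist", "herder", {"tree", "product"}),
        # external actors
        _node("trader", "Woman trader", soc, "female", "external", "trader", {"product"}),
        _node("consumer", "Consumer", soc, "unspecified", "external", "consumer", {"product"}),
        _node("visitor", "Visitor", soc, "unspecified", "external", "visitor", {"product"}),
        _node("person_in_hardship", "Person in hardship", soc, "unspecified", "external", "person_in_hardship", {"product"}),
        _node("relative", "Relative living in town", soc, "female", "external", "relative", {"product"}),
    ]


#: Social nodes at the product level of the stylized roster, in roster order.
_PRODUCT_SOCIAL = (
    "native_farmer_man",
    "native_woman_first",
    "native_woman_other",
    "chief",
    "helper_woman",
    "migrant_farmer_man",
    "migrant_woman_first",
    "migrant_woman_other",
    "migrant_youth",
    "pastoralist_woman",
    "trader",
    "consumer",
    "visitor",
    "person_in_hardship",
    "relative",
)


def nere_example_network() -> SENetwork:
    """A deterministic stylized network over :func:`nere_roster`.

    Authored so that the qualitative findings of the system it emulates hold
    as testable facts: the rights sub-network ({Right, Action}) is a DAG
    whose most dominant node is the native farmer man; the benefits
    sub-network ({Ecology, Contribution, Transfer}) has exactly one
    reciprocated reachable pair (land and animals, via pasture and manure)
    and women as its dominant social nodes; the harvested-seeds node carries
    the highest degree; pastoralists, youths, traders, consumers, visitors
    and people in hardship originate no link in either cascade selection.
    """
    L = LinkSpec
    links: list[LinkSpec] = [
        # --- rights: Right (person -> person) -------------------------------
        L("native_farmer_man", "native_woman_first", "Right", "tree", "harvest rights to first spouse"),
        L("native_farmer_man", "migrant_farmer_man", "Right", "land", "land access to migrants"),
        L("native_farmer_man", "pastoralist_man", "Right", "land", "grazing access"),
        L("chief", "migrant_farmer_man", "Right", "land", "chief allocates land"),
        L("native_woman_first", "native_woman_other", "Right", "tree", "first spouse shares rights"),
        L("native_woman_first", "helper_woman", "Right", "product", "access in return for help"),
        L("migrant_farmer_man", "migrant_woman_first", "Right", "tree", ""),
        L("migrant_woman_first", "migrant_woman_other", "Right", "tree", ""),
        L("migrant_farmer_man", "migrant_youth", "Right", "tree", ""),
        # --- rights: Action (person -> ecological) --------------------------
        L("native_farmer_man", "nere_tree", "Action", "land", "protect/plant/cut"),
        L("native_farmer_man", "land", "Action", "land", "cultivate"),
        L("migrant_farmer_man", "land", "Action", "land", "cultivate"),
        L("native_woman_first", "seeds_on_tree", "Action", "tree", "harvest"),
        L("native_woman_other", "seeds_on_tree", "Action", "tree", "harvest"),
        L("migrant_woman_first", "seeds_on_tree", "Action", "tree", "harvest"),
        L("migrant_woman_other", "seeds_on_tree", "Action", "tree", "harvest"),
        L("native_woman_first", "harvested_seeds", "Action", "product", "process into soumbala"),
        L("native_woman_other", "harvested_seeds", "Action", "product", "process"),
        L("migrant_woman_first", "harvested_seeds", "Action", "product", "process"),
        L("migrant_woman_other", "harvested_seeds", "Action", "product", "process"),
        # --- benefits: Ecology (ecological -> ecological) -------------------
        L("land", "nere_tree", "Ecology", "land", "nutrients and water"),
        L("land", "animals", "Ecology", "land", "pasture"),
        L("animals", "land", "Ecology", "land", "manure"),
        L("nere_tree", "seeds_on_tree", "Ecology", "tree", "pod production"),
        # --- benefits: Contribution (ecological -> person) ------------------
        L("nere_tree", "native_farmer_man", "Contribution", "land", "shade and fodder"),
        L("seeds_on_tree", "native_woman_first", "Contribution", "tree", "seeds to the harvester"),
        *[
            L("harvested_seeds", who, "Contribution", "product", "food and income")
            for who in _PRODUCT_SOCIAL
        ],
        # --- benefits: Transfer (person -> person, women instigate) ---------
        L("native_woman_first", "native_farmer_man", "Transfer", "product", "soumbala to husband"),
        L("native_woman_first", "pastoralist_woman", "Transfer", "product", "seeds for harvest help"),
        L("native_woman_first", "trader", "Transfer", "product", "sale"),
        L("native_woman_first", "visitor", "Transfer", "product", "gift"),
        L("native_woman_first", "person_in_hardship", "Transfer", "product", "gift"),
        L("native_woman_first", "relative", "Transfer", "product", "soumbala to daughter in town"),
        L("migrant_woman_first", "migrant_woman_other", "Transfer", "product", "sharing"),
        L("migrant_woman_first", "consumer", "Transfer", "product", "sale"),
        L("migrant_woman_first", "migrant_youth", "Transfer", "product", "sharing"),
        L("migrant_woman_first", "migrant_farmer_man", "Transfer", "product", "soumbala to husband"),
        L("native_farmer_man", "chief", "Transfer", "product", "customary gift"),
        # --- other reciprocating flows: Payment, Work -----------------------
        L("trader", "native_woman_first", "Payment", "product", "purchase"),
        L("consumer", "migrant_woman_first", "Payment", "product", "purchase"),
        L("migrant_farmer_man", "native_farmer_man", "Payment", "land", "land payment"),
        L("migrant_farmer_man", "chief", "Payment", "land", "allocation dues"),
        L("pastoralist_woman", "native_woman_first", "Work", "tree", "harvest help"),
        L("helper_woman", "native_woman_first", "Work", "product", "processing help"),
        L("migrant_youth", "migrant_farmer_man", "Work", "land", "field work"),
        L("native_woman_other", "native_woman_first", "Work", "tree", "harvest help"),
        L("migrant_woman_other", "migrant_woman_first", "Work", "tree", "harvest help"),
        L("pastoralist_man", "native_farmer_man", "Work", "land", "herding service"),
    ]
    roster = nere_roster()
    links += [
        L(n.id, n.id, "Coupling", "vertical", "same node across levels")
        for n in roster
        if len(n.levels) >= 2
    ]
    return SENetwork(roster, links)


# ---------------------------------------------------------------------------
# random generator

#: Category-compatible reverse type used when an arc is reciprocated.
_RECIP_TYPE: Mapping[str, str] = {
    "Right": "Work",
    "Action": "Contribution",
    "Ecology": "Ecology",
    "Contribution": "Action",
    "Transfer": "Payment",
    "Payment": "Transfer",
    "Work": "Payment",
}


@dataclass(frozen=True)
class GenConfig:
    """Parameters of the random network generator.

    Defaults mirror the study system the package is built around: 10, 11 and
    16 nodes at the land, tree and product levels and a per-level density
    inside the 0.19-0.29 band (0.24, its midpoint).

    Parameters
    ----------
    n_land, n_tree, n_product:
        Node counts per level (each >= 2).
    target_density:
        Expected fraction of realized directed arcs among the n*(n-1)
        possible arcs at each level.
    p_recip:
        Probability that a generated arc receives a reverse arc of a
        category-compatible type.  0 leaves the rights layer acyclic;
        1 symmetrizes every arc.
    p_type:
        Relative weights over the seven substantive link types; uniform by
        default (no per-type frequencies are reported for the system
        emulated, so uniformity is an explicit, arbitrary default).  When a
        mapping is given it is the whole distribution -- unlisted types get
        weight 0.  At each node pair the weights are renormalized over the
        types compatible with the endpoint categories; pairs whose
        compatible types all have weight 0 produce no link.
    p_female_source:
        Probability that a Transfer between a female and a non-female actor
        originates from the woman (women instigate most product flows in
        the system emulated).
    eco_fraction:
        Fraction of each level's generated nodes that are ecological.
    seed:
        Seed for the generator's random stream.
    """

    n_land: int = 10
    n_tree: int = 11
    n_product: int = 16
    target_density: float = 0.24
    p_recip: float = 0.3
    p_type: Mapping[str, float] | None = None
    p_female_source: float = 0.8
    eco_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_land", "n_tree", "n_product"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        for name in ("p_recip", "p_female_source", "eco_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if not 0.0 < self.target_density <= 1.0:
            raise ValueError("target_density must lie in (0, 1]")
        if self.p_type is not None:
            unknown = set(self.p_type) - set(SUBSTANTIVE_TYPES)
            if unknown:
                raise ValueError(f"unknown link types in p_type: {sorted(unknown)}")
            if any(w < 0 for w in self.p_type.values()):
                raise ValueError("p_type weights must be non-negative")


def _synthetic_roster(config: GenConfig, rng: np.random.Generator) -> list[NodeSpec]:
    """Level-disjoint roster with the configured per-level counts."""
    groups = ("native_farmer", "migrant_farmer", "pastoralist", "external")
    nodes: list[NodeSpec] = []
    for level, count in (
        ("land", config.n_land),
        ("tree", config.n_tree),
        ("product", config.n_product),
    ):
        n_eco = max(1, int(round(config.eco_fraction * count)))
        n_eco = min(n_eco, count - 1)  # keep at least one social node
        for i in range(count):
            if i < n_eco:
                nodes.append(
                    _node(f"{level}_eco{i}", f"{level} element {i}", "ecological",
                          "unspecified", "none", "element", {level})
                )
            else:
                gender = "male" if rng.random() < 0.5 else "female"
                group = groups[int(rng.integers(len(groups)))]
                nodes.append(
                    _node(f"{level}_soc{i}", f"{level} actor {i}", "social",
                          gender, group, "actor", {level})
                )
    return nodes


def _eligible_types(
    src_cat: str, tgt_cat: str
) -> tuple[str, ...]:
    if src_cat == "social" and tgt_cat == "social":
        return ("Right", "Transfer", "Payment", "Work")
    if "ecological" in (src_cat, tgt_cat) and "social" in (src_cat, tgt_cat):
        return ("Action", "Contribution")
    return ("Ecology",)


def generate(config: GenConfig, roster: Sequence[NodeSpec] | None = None) -> SENetwork:
    """Draw a random multilayer network, reproducibly for a fixed seed.

    For every unordered pair of nodes sharing a level, an arc is created
    with probability ``q = 2 d / (1 + p_recip)`` (``d`` the target density),
    so the expected number of directed arcs at each level is exactly
    ``d * n * (n - 1)``; each created arc is then reversed with probability
    ``p_recip`` using a category-compatible reverse type.  Arc direction
    follows a latent dominance order drawn once per network -- social nodes
    above ecological ones, shuffled within blocks -- except that
    Contribution arcs always run ecological -> social and Transfer arcs are
    biased to originate from women.  ``Right`` and ``Action`` arcs follow
    the order strictly, so ``p_recip = 0`` leaves the rights sub-network
    acyclic by construction.

    ``roster`` overrides the generated level-disjoint roster (e.g. with
    :func:`nere_roster`, whose nodes span levels); vertical Coupling records
    are added for every multi-level node.

    Raises ``ValueError`` when the target density is infeasible for the
    requested reciprocity (``q > 1``).
    """
    rng = np.random.default_rng(config.seed)
    q = 2.0 * config.target_density / (1.0 + config.p_recip)
    if q > 1.0:
        raise ValueError(
            f"target_density {config.target_density} infeasible at "
            f"p_recip {config.p_recip}: pair probability {q:.3f} > 1"
        )
    nodes = list(roster) if roster is not None else _synthetic_roster(config, rng)
    by_id = {n.id: n for n in nodes}

    # latent dominance order: social block above ecological block, each
    # shuffled once; rank[i] < rank[j] means i dominates j
    social = [n.id for n in nodes if n.category == "social"]
    eco = [n.id for n in nodes if n.category == "ecological"]
    rng.shuffle(social)
    rng.shuffle(eco)
    rank = {nid: i for i, nid in enumerate(social + eco)}

    # an explicit p_type is the whole distribution: unlisted types get 0
    weights = dict.fromkeys(SUBSTANTIVE_TYPES, 0.0 if config.p_type else 1.0)
    if config.p_type:
        weights.update(config.p_type)

    links: list[LinkSpec] = []
    for level in LEVELS:
        members = sorted(n.id for n in nodes if level in n.levels)
        for i, u in enumerate(members):
            for v in members[i + 1 :]:
                if rng.random() >= q:
                    continue
                cu, cv = by_id[u].category, by_id[v].category
                eligible = _eligible_types(cu, cv)
                w = np.array([weights[t] for t in eligible], dtype=float)
                if w.sum() == 0:
                    continue
                ltype = eligible[int(rng.choice(len(eligible), p=w / w.sum()))]
                src, tgt = (u, v) if rank[u] < rank[v] else (v, u)
                if ltype == "Action" and by_id[src].category != "social":
                    src, tgt = tgt, src
                elif ltype == "Contribution":
                    src, tgt = (u, v) if cu == "ecological" else (v, u)
                elif ltype == "Transfer":
                    genders = (by_id[src].gender, by_id[tgt].gender)
                    if genders == ("male", "female") or (
                        genders[0] == "unspecified" and genders[1] == "female"
                    ):
                        if rng.random() < config.p_female_source:
                            src, tgt = tgt, src
                    elif genders[0] == "female" and genders[1] != "female":
                        if rng.random() >= config.p_female_source:
                            src, tgt = tgt, src
                links.append(LinkSpec(src, tgt, ltype, level))
                if rng.random() < config.p_recip:
                    links.append(LinkSpec(tgt, src, _RECIP_TYPE[ltype], level))

    links += [
        LinkSpec(n.id, n.id, "Coupling", "vertical")
        for n in nodes
        if len(n.levels) >= 2
    ]
    return SENetwork(nodes, links)
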