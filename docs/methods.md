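# Methods

## The network model

A social–ecological network here is a directed multilayer network over a
single roster: one vertex per actor or ecological element, carrying a
*set* of level memberships (land, tree, product) rather than one replica
per level. Links of different types between the same ordered pair are all
retained in the container — they drive the dyad census — but collapse onto
a single arc when the network is flattened into a graph, because degree is
reported once per node and hierarchy is a property of reachability, not of
link multiplicity. The "vertical self-coupling" of a node that appears at
several levels is stored as a `Coupling` record (source = target, level =
`vertical`) for provenance and excluded from every metric: after
flattening it would be a self-loop and carry no relational information.

Endpoint-category expectations per link type (Right/Transfer/Payment/Work
social→social, Action social→ecological, Ecology ecological→ecological,
Contribution ecological→social) are enforced as *warnings*, not errors.
Field-coded data legitimately bend them — labour between two people repaid
"in contribution", for instance — so a hard error would reject genuine
observations, while silence would hide coding slips.

Controlled vocabularies are case-insensitive on input and canonical on
output. The CSV dialect is UTF-8, comma-separated, header mandatory; the
`levels` cell of a node row joins memberships with `|`.

## Indicators

*Density* at a level is the number of distinct directed arcs divided by
n(n−1), the number of ordered pairs; with fewer than two member nodes it
is reported as `None` (undefined), never 0. Parallel links therefore do
not inflate density, but the raw link count (`n_links`) is reported
alongside. *Reciprocity* is computed on links: a link counts as
reciprocated when **any** reverse link exists at the same level,
regardless of type, because mixed-type exchanges (Transfer answered by
Payment, Work answered by a granted Right) are exactly the reciprocal
relations of interest. Consequently reciprocity is 1 on any symmetrized
network and 0 on any network without reverse arcs.

Gender composition is reported as fractions over *gendered* social nodes
only; rounding to percentages is left to presentation.

The *dyad census* inventories, for every connected unordered pair, the
combination of (relative direction, type) entries over all links between
the pair, pooled across levels and deduplicated. The profile is
direction-symmetric: of a pair's two orientations the one whose forward
entries lead is the canonical one, so relabelling nodes or swapping the
stored orientation never changes a profile.

## Hierarchy, dominance, layers

The Krackhardt hierarchy score is computed from the reachability relation
R (per-source graph traversal; tests cross-check it against an independent
matrix-power transitive closure). Over unordered pairs {u, v} with u R v
or v R u, the score is 1 minus the fraction of symmetric pairs, evaluated
in exact rational arithmetic before conversion to float. Pairs with no
reachability in either direction are excluded from the denominator by
default (`pair_universe="reachable"`): cascade sub-networks keep the full
roster, and counting isolated pairs would dilute the score of a perfectly
hierarchical sub-network below 1. The all-pairs convention remains
available (`pair_universe="all"`) since the alternative cannot be ruled
out for historically reported values; the default is the one under which
a rights cascade that is a DAG scores exactly 1. An arc-free graph has no
reachable pair and the score is undefined — an explicit error from
`krackhardt_hierarchy`, a `None` marker (and CLI exit code 3) from
`cascade`.

*Dominance* of a node is |R(v)|, the number of distinct other nodes it
reaches; it is invariant under adding arcs already implied by
reachability. *Layers* for drawing are assigned on the condensation of
the graph (strongly connected components collapsed, guaranteeing
acyclicity): maximal-dominance components sit at depth 0 — they can have
no predecessor, since a predecessor would reach strictly more nodes — and
every other component takes the longest-path depth from its predecessors,
with components unreachable from any top node starting at depth 1. Layer
0 therefore contains exactly the dominance argmax. Rank ties anywhere are
broken by node id, lexicographically, for deterministic output.

## Layouts

The force-directed mode delegates to the Fruchterman–Reingold spring
embedding (seeded, hence reproducible), with node sizes equal to
all-degree. The layered mode places a cascade at y = −depth and orders
each layer by two barycenter sweeps (one downward, one upward) over
neighbours in the adjacent layer. Exact layered crossing minimisation is
NP-hard; two sweeps are a documented approximation, adequate because the
drawing is presentational — coordinates, not pixels, are the tested
artifact, and the property tested is that the sweeps never increase the
crossing count relative to the initial id-sorted order on exhaustively
countable graphs. Rendering to SVG/PNG is a thin matplotlib layer.

## Synthetic data

The generator serves two needs: a **fixed stylized network**
(`nere_example_network`) and **seeded random networks** (`generate`).

The stylized roster has 16 social actors and 5 ecological elements with
10/11/16 nodes at the land/tree/product levels; gendered membership gives
a two-thirds male land level and female-majority tree (62.5 %) and
product levels, echoing the pattern of the system it emulates (the
product-level female share is higher than in that system — the stylized
roster is small and every spouse, trader and helper at that level is a
woman). Its curated link set makes the qualitative structure of the
emulated system *testably true*: the rights selection forms a DAG topped
by the native farmer man; the benefits selection contains exactly one
reciprocated reachable pair (the land–animals pasture/manure loop) with
women as the dominant social nodes; harvested seeds carry the highest
degree; pastoralists, youths, traders, consumers, visitors and people in
hardship originate no link in either cascade selection. It is a synthetic
stand-in, not a coded field dataset, and aggregate statements about it
(number of connected pairs, per-level link counts) are not expected to
match any real community's network exactly.

The random generator draws, per level and per unordered node pair, an arc
with probability q = 2d/(1+p_recip) (d the target density, default 0.24 —
the midpoint of the 0.19–0.29 band the emulated system reports), then
reverses it with probability `p_recip` using a category-compatible
reverse type (Transfer↔Payment, Action→Contribution, Work→Payment,
Ecology→Ecology, Right→Work). The expected number of directed arcs per
level is then exactly d·n(n−1). Link types are drawn from `p_type`
(uniform by default — no per-type frequencies are reported for the
emulated system, so uniformity is an explicit, arbitrary choice)
restricted to the types compatible with the pair's categories. Arc
direction follows a latent dominance order drawn once per network (social
block above ecological, shuffled within blocks); `Right`/`Action` arcs
follow it strictly, so `p_recip = 0` leaves the rights sub-network
acyclic and its hierarchy score at exactly 1, while `p_recip = 1`
symmetrizes everything and drives the full-network score to 0.
Contribution arcs always run ecological→social, and Transfer arcs
originate from the female endpoint with probability 0.8
(`p_female_source`), letting the women-on-top benefits pattern emerge as
a testable tendency. Generated rosters are level-disjoint (each random
node lives at one level), which makes per-level counts exact by
construction; multilayer membership and Coupling records are exercised by
passing the stylized roster to `generate`.

What the generator does **not** emulate: any particular observed network
(fidelity targets are aggregate — counts, density band, hierarchy
endpoints), degree heterogeneity beyond what uniform pair sampling
produces, cross-level correlation of ties, and any household or kinship
structure among actors. Passing tests therefore demonstrate correctness
of the computations and of the qualitative mechanisms, not fidelity to
any particular field dataset.

## Problem sizes and numerics

Default test and reproduction sizes are kept small because the
quantities of interest are exact at any size: 100 generator draws for
the two score-calibration checks, 200 random digraphs of ≤ 8 nodes for
oracle equivalence (where brute-force closure is exhaustive), 50 seeds
per reciprocity setting for the monotonicity check. Scores are exact
rationals until the final float conversion, so "equals 1", "equals 0"
and "equals 0.98" are exact comparisons, not tolerances. Text reports
round scores to two decimals; JSON carries full precision.
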