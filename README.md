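# senet — multilayer social–ecological network analysis

`senet` analyses **social–ecological networks (SENs)**: directed networks
whose nodes are both social actors (farmers, spouses, chiefs, traders,
consumers) and ecological elements (land, animals, trees, seeds), built to
study how rights over, and benefits from, a shared tree resource circulate
through a community. The motivating system is the West African parkland
around the néré tree (*Parkia biglobosa*), whose seeds women ferment into
the condiment *soumbala* — but the machinery is generic.

It is aimed at ethnoecologists and researchers of natural-resource
governance who have coded qualitative field data into node and link tables
and want the quantitative side of the analysis: level-wise indicators,
hierarchy scores, dominance rankings and drawing coordinates.

## The model

A network is a roster of typed nodes and a multiset of directed links.
Each node carries a category (social/ecological), gender, ethnic/role
group, role tag, and a non-empty set of **level** memberships among
*land*, *tree* and *product* — the three arenas where interactions happen.
Each link carries one of seven substantive types:

| type | flow |
|---|---|
| Right | rights passed person → person |
| Action | person acts on an ecological element |
| Ecology | ecological → ecological flow |
| Contribution | ecological element supplies a benefit to a person |
| Transfer | person passes a product/benefit to a person |
| Payment | monetary flow |
| Work | labour supplied |

plus vertical *Coupling* records tying a multi-level node to itself
(excluded from all metrics).

Key quantities, for a directed graph `G` with reachability relation `R`
(directed paths of length ≥ 1, self-reachability excluded):

- **density** at a level: distinct directed arcs / *n(n−1)*;
- **reciprocity**: share of links answered by a reverse link of any type at
  the same level;
- **Krackhardt hierarchy score**
  `h(G) = 1 − |{{u,v} : uRv ∧ vRu}| / |{{u,v} : uRv ∨ vRu}|` —
  1 for a fully hierarchical (acyclic-reachability) network, 0 when every
  reachable pair is mutual;
- **dominance** of `v`: the number of distinct other nodes `v` reaches;
- the **cascade of rights** (`{Right, Action}`) and **cascade of benefits**
  (`{Ecology, Contribution, Transfer}`): sub-networks on the full roster,
  scored with `h`, ranked by dominance, and layered for top-down drawing.

## Worked example

```python
from senet import cascade, level_summary, nere_example_network

network = nere_example_network()   # bundled stylized 21-node SEN
for level in ("land", "tree", "product"):
    s = level_summary(network, level)
    print(level, s.n_nodes, s.n_links, round(s.density, 2), s.gender_share)

rights = cascade(network, "rights")
benefits = cascade(network, "benefits")
print(rights.hierarchy, benefits.hierarchy)
print(rights.ranking(social_only=True).head(3))
```

Running `python examples/02_cascades.py` prints:

```
rights   hierarchy: 1.00
benefits hierarchy: 0.98
full     hierarchy: 0.26

top of the rights cascade (dominance = nodes reachable):
                    dominance  layer  rank
node
native_farmer_man          12      0     1
chief                       7      1     2
migrant_farmer_man          6      2     3

top of the benefits cascade (social nodes):
                     dominance  layer  rank
node
native_woman_first           7      1     1
migrant_woman_first          4      1     2
native_farmer_man            1      2     3
```

Read: the rights sub-network is perfectly hierarchical (score 1.00 — no
rights ever flow back up), topped by the native farmer man, who can pass
rights, directly or indirectly, to 12 other nodes. The benefits
sub-network is *nearly* hierarchical (0.98: a single reciprocated
reachable pair, the land–animals pasture/manure loop) and its dominant
social nodes are women — the same actors hold opposite positions in the
two cascades. The full network, with all seven link types, is far less
hierarchical (0.26) because market exchanges and labour reciprocate flows.

Other entry points: `examples/01_build_and_summarize.py` (level summaries
and the dyad census of link-type combinations),
`examples/03_synthetic_networks.py` (the seeded random generator and how
reciprocity dissolves hierarchy), `examples/04_layouts.py` (force-directed
and layered drawing coordinates). A thin CLI mirrors the library:
`senet generate | summarize | census | cascade | layout --help`.

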