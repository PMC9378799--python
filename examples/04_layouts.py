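"""Compute drawing coordinates for the full network and a cascade.

The force-directed layout places linked nodes near each other (node size =
degree); the layered layout stacks a cascade top-down, most dominant nodes
at y = 0, with two barycenter sweeps to reduce arc crossings (node size =
dominance).  Coordinates are printed; rendering to SVG is one extra call
(senet.render).
"""

from senet import (
    cascade,
    flatten,
    force_layout,
    hierarchical_layout,
    nere_example_network,
)

network = nere_example_network()

force = force_layout(flatten(network), iterations=50, seed=7)
frame = force.to_frame().sort_values("size", ascending=False)
print("force-directed layout, five highest-degree nodes:")
print(frame.head(5).round(2))

rights = cascade(network, "rights")
layered = hierarchical_layout(rights)
print("\nlayered rights cascade (y = -depth, size = dominance):")
print(layered.to_frame().sort_values(["y", "x"], ascending=[False, True]).head(8).round(2))
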