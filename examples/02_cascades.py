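"""Extract and score the cascades of rights and benefits.

The rights cascade keeps Right and Action links (who passes rights to whom,
who acts on which ecological element); the benefits cascade keeps Ecology,
Contribution and Transfer links (how benefits are produced and circulate).
A Krackhardt hierarchy score of 1 means no reachable pair of nodes is
mutually reachable -- a strict top-down flow; dominance counts how many
other nodes a node can reach along directed links.
"""

from senet import cascade, compare_positions, nere_example_network

network = nere_example_network()
rights = cascade(network, "rights")
benefits = cascade(network, "benefits")
full = cascade(network, "full")

print(f"rights   hierarchy: {rights.hierarchy:.2f}")
print(f"benefits hierarchy: {benefits.hierarchy:.2f}")
print(f"full     hierarchy: {full.hierarchy:.2f}")

print("\ntop of the rights cascade (dominance = nodes reachable):")
print(rights.ranking(social_only=True).head(3))
print("\ntop of the benefits cascade (social nodes):")
print(benefits.ranking(social_only=True).head(3))

# the same actors hold very different positions in the two cascades:
# rank 1 = most dominant within the social roster
table = compare_positions(rights, benefits, social_only=True)
print("\npositions in both cascades (rank_a = rights, rank_b = benefits):")
print(table.head(6))
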