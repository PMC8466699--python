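"""Build a median-joining haplotype network.

Three haplotypes mutually two mutations apart are best explained by an
unobserved central intermediate: the median-joining step infers it.
"""

from mitosweep import median_joining

net = median_joining(["AAT", "ATA", "TAA"])
for node, data in net.graph.nodes(data=True):
    print(f"{node}: {data['sequence']} ({data['kind']})")
for u, v, w in net.graph.edges(data="weight"):
    print(f"  {u} -- {v}  ({w} mutation{'s' if w > 1 else ''})")
print(f"total network cost: {net.total_cost} (vs 4 for a spanning tree "
      "without the inferred median)")
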