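"""Base-node determination and branch routes on a two-sprout skeleton.

Two sprouts are spuriously joined by a near-horizontal segment left over
from the cell-gel interface.  Base-node determination detects it by its
small rise/run ratio, removes it, and route enumeration then reports one
route per (base, tip) pair.
"""

from sprouttrack import BranchingConfig, SkeletonGraph, determine_base_nodes, enumerate_branch_routes

g = SkeletonGraph()
coords = {1: (100, 390), 2: (102, 375), 3: (200, 385), 4: (105, 300),
          5: (205, 330), 6: (80, 240), 7: (130, 250), 8: (115, 190), 9: (160, 200)}
for nid, (x, y) in coords.items():
    g.add_node(x, y, node_id=nid)
for a, b in [(1, 2), (2, 4), (4, 6), (4, 7), (7, 8), (7, 9), (3, 5), (2, 3)]:
    g.add_segment(a, b)
g.relabel_roles(preserve_base=False)

bases, removed = determine_base_nodes(g, BranchingConfig(tau=0.5, d_base=20))
routes = enumerate_branch_routes(g, bases)

print(f"base nodes: {bases}   (removed artificial connector segments: {removed})")
for i, r in enumerate(routes, 1):
    print(f"branch {i}: {r.nodes}  (sprout {r.sprout_id}, length {r.length:.0f} px)")
print("the connector 2-3 is nearly parallel to the monolayer (ratio < tau=0.5), so")
print("it is removed and the graph splits into two sprouts with bases 1 and 3.")
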