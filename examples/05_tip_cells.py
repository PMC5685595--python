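"""Tip-cell identification: projection beats end-point distance.

A branch grows along +y and ends at (0, 10).  Cell L sits laterally,
nearest to the end point; cell T has migrated ahead along the growth
direction.  Picking the nearest cell misidentifies L as the tip; the
projection criterion p_i = (e-s).(x_i-s)/|e-s| correctly selects T.
"""

import numpy as np
import pandas as pd

from sprouttrack import BranchRoute, identify_tip_cell

poly = np.array([[0.0, 0.0], [0.0, 10.0]])
route = BranchRoute(nodes=[1, 2], polyline=poly, length=10.0, mean_radius=4.0,
                    node_positions=poly.copy())
cells = pd.DataFrame({"cell_id": ["L", "T"], "x": [3.0, 0.0], "y": [9.5, 13.5]})

d_end = np.hypot(cells.x - 0.0, cells.y - 10.0)
nearest = cells.cell_id[d_end.idxmin()]
tip, projection = identify_tip_cell(route, cells, n_tip=3)

for cid, d in zip(cells.cell_id, d_end):
    print(f"cell {cid}: distance to end point {d:.2f} px")
print(f"distance-only choice: {nearest}   projection choice: {tip} (p = {projection:.1f})")
print("L is nearest to the end point but lateral; T leads along the growth")
print("direction, so T heads the branch.")
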