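"""Junction helper structures for adjacent targets in different RT intents.

When two targets in separately optimized plans sit closer than 5 mm in the
superior-inferior direction, the optimization target of the superior intent
is pulled 5 mm off the neighbour's 3 cm lateral/AP expansion, and a thin
avoidance band caps the composite hotspot between them.
"""

from ldrtplan.core import Grid, StructureMask
from ldrtplan.plangeom import derive_junction_structures, detect_junctions, partition_intents

import numpy as np

grid = Grid((40, 40, 600), (4.0, 4.0, 1.0))
x, y, z = grid.meshgrid()


def si_box(z_lo, z_hi, name):
    m = (np.abs(x - 80) <= 30) & (np.abs(y - 80) <= 30) & (z >= z_lo) & (z <= z_hi)
    return StructureMask(name, m, grid, role="PTV")


a = si_box(360, 560, "PTV_a")   # superior target
b = si_box(150, 356, "PTV_b")   # inferior target, 4 mm gap

intents = partition_intents([b, a], [(-1e9, 1e9, "abdomen")])
flags = detect_junctions(intents, [a, b])
print(f"{len(intents)} intents; junction flags: "
      f"{[(f.target_a, f.target_b, f.gap_mm) for f in flags]}")

js = derive_junction_structures(a, b)
print(f"PTV_a_Opti: {js.ptv_a_opti.volume_cc:.1f} cc "
      f"(PTV_a is {a.volume_cc:.1f} cc); SI extent {js.ptv_a_opti.extent_mm(2)}")
print(f"Junction_avoid band: {js.junction_avoid.volume_cc:.1f} cc, "
      f"SI extent {js.junction_avoid.extent_mm(2)}")
print("goals:")
for g in js.extra_goals:
    print("  ", g.describe())
# The cropped optimization target keeps each intent's dose falloff out of
# its neighbour; the avoidance band goal (V_2Gy <= 10%) caps the junction
# hotspot when the two independently optimized doses add up.
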