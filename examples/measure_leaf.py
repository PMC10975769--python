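"""Measure leaf length, perimeter and area and compare to analytic truth.

Length follows the lifted midrib polyline (chord divided into n1 parts,
each division point lifted to the surface), perimeter sums distances
around the alpha-shape outline, and area sums the triangles of a
multi-radius ball-pivoting mesh.
"""

import numpy as np

from rkmd.measure import measure_leaf
from rkmd.synthetic import LeafSpec, generate_leaf

for label, spec in [
    ("flat ellipse (a=30, b=15)",
     LeafSpec(semi_major=30.0, semi_minor=15.0, density=12.0, noise_sigma=0.0)),
    ("bent leaf (Rc=50 mm, 60 deg arc)",
     LeafSpec(semi_major=30.0, semi_minor=15.0, bend_radius=50.0, bend_angle=60.0,
              density=12.0, noise_sigma=0.0)),
]:
    cloud, truth = generate_leaf(spec, seed=7)
    m = measure_leaf(cloud)
    print(label, f"({len(cloud)} points)")
    for name, got, want, unit in [
        ("length", m.length, truth.length, "mm"),
        ("perimeter", m.perimeter, truth.perimeter, "mm"),
        ("area", m.area, truth.area, "mm^2"),
    ]:
        print(f"  {name:9s} {got:9.2f} {unit:5s} truth {want:9.2f} "
              f"({100 * (got / want - 1):+.2f}%)")
# The bent leaf's true length is the cylinder arc Rc * angle = 52.36 mm;
# the polyline recovers it where a straight chord would read only ~50 mm.
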