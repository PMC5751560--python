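"""Detect junction vertices on a merged contour and cut it there.

Samples the merged outline of a touching ellipse pair, extracts the
dominant-point sequence, labels each vertex by its cross angle (acute =
nonsmooth junction), splits the cycle, and reports the longest smooth
arc — one object's boundary.
"""

import numpy as np

from kdomseg import (
    extract,
    label_vertices,
    longest_smooth_subsequence,
    split,
    synth,
)

spec = synth.touching_spec(seed=5)
points, truth = synth.sample_boundary(spec)
seq = extract(points)
labeled = label_vertices(seq)

print(f"{len(seq)} dominant points; vertex angles (degrees):")
for v, ang, ns in zip(seq.vertices, np.degrees(labeled.angles), labeled.nonsmooth):
    mark = "  <- nonsmooth (junction)" if ns else ""
    print(f"  ({v[0]:6.1f}, {v[1]:6.1f})  {ang:6.1f}{mark}")
print("true junctions:", np.round(truth.junctions, 1).tolist())

arcs = split(labeled)
print(f"\nsplit into {len(arcs)} arcs of sizes {[len(a) for a in arcs]}")
best = longest_smooth_subsequence(labeled)
print(f"longest smooth arc: {len(best)} vertices, "
      f"polyline length {best.length:.1f} px")
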