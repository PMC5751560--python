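# Methods

## Model and procedure

`kdomseg` approximates an unordered planar point set `P` — in practice
a connected component of edge pixels — by a cyclic *geometric
sequence* of k dominant points. The underlying assumption is that `P`
densely samples a simple closed curve (or a merged outline of a small
number of such curves) at roughly unit spacing, with additive
isotropic position noise.

All proximity reasoning uses one primitive, the *point-line-segment
distance* `‖p−a‖ + ‖p−b‖`: `p` lies on segment `ab` exactly when this
sum equals `‖a−b‖`, and "approximately on" means within the band
`‖p−a‖+‖p−b‖ ≤ ‖a−b‖ + max(ε‖a−b‖, band_floor)`. The band is an
ellipse with foci `a, b`; its half-width at mid-segment is about
`(‖a−b‖/2)·√(2ε)`, which is worth keeping in mind: a corner whose
sagitta over its neighbours' chord is below that half-width is
*geometrically indistinguishable from a straight edge* at tolerance ε.
That observation drives several choices below.

The extractor proceeds exactly as sketched in the README: farthest
pair, unconditional third point, then balance-selected insertions of
max/min/median sum-distance candidates while insertable, with
reduction + per-open-pair recursion when not. Details that the
high-level description leaves open, and how this implementation
resolves them:

- **Slot choice.** An insertable candidate could fill any open pair.
  The length criterion picks the slot adding the least cyclic
  polyline length (the shortest tour through a fixed vertex set is
  the simple, non-crossing order); among nearly tied slots the first
  one that keeps the ring simple wins, which matters beside the
  narrow neck of a touching pair. The count criterion instead
  maximises how many input points the augmented polyline covers.
- **Closed tags.** Both pairs created by an insertion are immediately
  tested for closedness: the points within the band of the pair's
  segment are projected onto it and must chain-cover it with no
  interior gap above `gap_tol`; gaps within `2·gap_tol` of either end
  may reach `2·gap_tol`, because a neighbouring closed pair's removal
  legitimately eats a few points past a shared corner.
- **Reduction.** Points in the band of any closed pair are removed
  (with twice the noise floor, so borderline stragglers do not leak
  into other subsets); the survivors are assigned to open pairs. The
  assignment is geodesic: a radius-4 px neighbour graph over the
  points approximates the boundary, and each point goes to the pair
  minimising `d(p,u) + d(p,w) − d(u,w)` along that graph, with disks
  around all *other* sequence vertices blocked so paths cannot run
  through foreign arcs. Euclidean band excess is the fallback for
  unreachable points. Pure spatial criteria mis-assign points
  wherever the boundary folds close to itself (the touching-pair
  neck); the geodesic criterion follows the curve instead.
- **Anchored recursion.** A child works on the subset of one open
  pair `(u, w)`; its sequence is initialised to exactly that pair,
  with the reverse pair `(w, u)` born closed — it is the parent's
  chord, not boundary, so nothing may be inserted into it and it
  must not swallow points during the child's own reductions. The
  child's cycle is spliced back by cutting it at `u` and `w` and
  taking the path with more interior vertices.
- **Straight-subset base case.** If even the sum-distance argmax of a
  subset lies inside the initial pair's band, the subset is a 1-piece
  polyline and the pair itself is returned — otherwise the argmax
  lands next to an endpoint (on a straight segment the score is
  maximal at the ends) and breeds sliver triangles.
- **Cleanup.** After the recursion: vertices inside their neighbours'
  band or within `dev_tol` of the neighbour chord are pruned (by the
  insertability definition they are not dominant); vertices within
  `dev_tol` of an earlier vertex are merged (two discoveries of one
  feature); while the ring self-intersects the sharpest vertex is
  dropped (the output contract is a simple polygon). Finally each
  vertex is optionally relocalised to the intersection of total-least-
  squares line fits of its two incident edges within a 12-px window,
  which averages the point noise out of the raw argmax position.

### Subdivision and the pipeline

A vertex is *nonsmooth* when its cross angle is below
`angle_threshold` (default π/2 — the literal acute/obtuse boundary;
real junction angles vary, so it is configurable). Cutting the cycle
at nonsmooth vertices gives one arc per touching object; each cut
vertex terminates the two adjacent arcs. The image pipeline chains
Canny edges (thresholds as fractions of the normalised intensity
range), 8-connected components with nearby components merged within
`merge_radius` (a weak-gradient crease interrupts the ring), component
selection, extraction, subdivision, and closing: a full smooth cycle
is interpolated by a periodic cubic spline through its dominant points
(a straight-edged polygon undercuts every arc by its sagitta, which
alone costs ~0.1 IoU on an ellipse), while split arcs are closed by a
least-squares ellipse fit (embryos are ellipsoidal) with a chord
fallback for degenerate fits.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `eps` | 0.02 | – | relative collinearity band; 0.01–0.05 sensible |
| `band_floor` | 2.0 | px | absolute band minimum; on short segments the relative band would be tighter than the point noise |
| `gap_tol` | 4.0 | px | max interior gap in a closedness chain cover; with 1-px spacing and 0.5-px jitter the largest gap on a ~100-px edge routinely reaches 3 px, so 3 would misclassify clean edges |
| `dev_tol` | 3.0 | px | vertex pruning/merging deviation tolerance |
| `confidence_mode` | length | – | slot ranking: cyclic length (cheap) or point-cover count |
| `measure_mode` | max_min_median | – | which candidate measures participate |
| `max_recursion_depth` | 4 | – | reduction recursion cap |
| `min_subset_size` | 5 | – | below this a subset is its farthest pair |
| `refine` | on | – | TLS corner relocalisation |
| `angle_threshold` | π/2 | rad | nonsmooth (junction) boundary |
| `canny_sigma` | 1.4 | px | edge smoothing; 2.0 blurs away a 2–4-px crease |
| `merge_radius` | 3.0 | px | join broken edge components |

## Synthetic data

The generator emulates the geometric situations the method targets,
at edge-map scale (1-px spacing, 0.5-px jitter, both configurable);
every spec is bit-reproducible from its seed.

- **Convex m-gons** (m = 3…8, circumradius 80 px): radial corner
  perturbation is rejection-sampled so the polygon stays convex and
  every corner keeps relative band excess ≥ 0.06 over its neighbours'
  chord — a corner inside the ε band is by definition not a dominant
  point, so shapes violating this are outside the method's resolvable
  class, not hard instances of it.
- **Ellipses** (semi-axes ~45–62 × 22–32 px) for smooth convex
  contours.
- **Bean shapes**: dimpled limaçons `r(θ) = R(c − cosθ)` with
  `c ∈ [1.3, 1.7]` (dimpled for 1 < c < 2), which have exactly two
  inflection points — the concave-but-single-object case.
- **Touching pairs**: two round-ish ellipses (aspect 0.5–0.62) lying
  side by side lengthwise — offset perpendicular to the shared long
  axis — with a shallow 2–4-px contact lens. This regime is chosen
  deliberately: the crease angle of a shallow lens tends to zero at
  tangency and reopens at rate ~2s/ρ with arc distance s, where ρ is
  the wall curvature radius (a²/b for broadside contact), so broadside
  stacking is the configuration in which junctions measured at
  dominant-point spacing are genuinely acute. Specs are validated at
  construction (exactly 2 boundary intersections; both junction
  angles ≤ 75° at 16-px spacing). Tip-to-tip or deeply overlapping
  pairs yield obtuse junction angles at any realistic vertex spacing
  and therefore are not "touching" in the sense the subdivision step
  can detect.
- **Rendered scenes** (192×192, background 30, objects 160/200,
  Gaussian noise σ = 6 gray levels): touching pairs render at a
  single gray level so the edge detector sees one merged silhouette —
  the situation the method exists for. Truth masks are per-object
  full-ellipse fills (the lens belongs to both).

What passing on this data does *not* show: robustness to textured
interiors (gene-expression staining), broken or cluttered edge maps
beyond small crease gaps, multi-object (>2) junctions, or strongly
non-ellipsoidal objects; real intensity structure is emulated only as
a flat fill plus Gaussian noise.

## Numerical choices and degenerate inputs

Ties in every argmax/argmin (farthest pair, candidates, slots,
ratios) break to the lowest point/slot index, so runs are
deterministic. Exact duplicate points collapse at `PointSet`
construction; zero-length segments and coincident-neighbour angles
raise. A candidate coinciding with a slot endpoint gets balance ratio
0 and is never selected. Sets smaller than `min_subset_size` return
their farthest pair. Band comparisons carry a 1e-9 absolute slack so
exactly-on-segment points are inside at ε = 0. The Fermat point uses
the equilateral-triangle construction with the ≥120° vertex rule and
rejects collinear triples.

## Evaluation protocol

An object counts as detected when its predicted mask overlaps the
ground-truth mask with IoU > 0.9 (IoU chosen as the symmetric standard
overlap measure); an image succeeds when all its objects are detected.
Each ground-truth mask is greedily matched to its best-overlapping
predicted contour. Pipeline errors on an image are recorded as
failures without aborting the batch.

## Known limitations

- The acute-junction dichotomy holds only when dominant points sit
  close enough to the junction relative to the crease depth; slim
  tip-to-tip contacts or deep overlaps defeat it (see above).
- The geodesic assignment assumes the edge map is locally chain-like;
  thick (multi-pixel) edges or dense clutter would distort the
  neighbour graph.
- Recursion depth is capped; pathological nested concavity beyond
  `max_recursion_depth` is approximated by chords.
- Sequence subdivision emits every arc between nonsmooth vertices;
  for >2 touching objects the arcs are returned as-is with no
  reasoning about which arcs belong to one object.
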