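"""k-dominant point extraction.

Polygonal approximation of an unordered 2-D point set (typically a
connected component of edge pixels) by a cyclic sequence of *dominant
points*.  The extractor

1. initialises with the farthest pair of points,
2. adds the point maximising the total distance to the current
   dominant points (the sum-distance score),
3. then repeatedly proposes up to three candidates — the argmax, argmin
   and median of the sum-distance score — picks the one whose placement
   between its best pair of neighbours is most *balanced*, and inserts
   it while it stays within a relative tolerance band of an open pair,
4. and when the selected candidate falls outside every open pair's
   band, removes the points already covered by closed pairs, partitions
   the remainder among the open pairs, recurses on each part and
   splices the child sequences back into their slots.

The max measure drives vertices of convex shapes; the min measure
reaches the waist of two touching smooth objects (the discrete
geometric-median idea); the median measure responds to inflection
points that are neither local maxima nor minima of the score.  The
divide-and-conquer reduction handles concave polygons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .geometry import (
    PointSet,
    confidence_count,
    confidence_length,
    is_insertable,
)
from .sequence import CandidateInsertion, DominantSequence, Measure

__all__ = [
    "ExtractionConfig",
    "ExtractionStats",
    "farthest_pair",
    "sum_distance_scores",
    "candidates",
    "best_slot",
    "balance_ratio",
    "select_candidate",
    "insert",
    "test_closedness",
    "reduce_point_set",
    "simplify",
    "refine_vertices",
    "extract",
    "extract_with_stats",
]

_MEASURE_PRIORITY = {Measure.MAX: 0, Measure.MIN: 1, Measure.MEDIAN: 2}


@dataclass
class ExtractionConfig:
    """Tunable parameters of the extractor.

    eps
        Relative tolerance of the collinearity band (insertability and
        closedness tests).  Dimensionless; sensible range 0.01-0.05.
    confidence_mode
        'length' ranks insertion slots by the cyclic polyline length
        (cheap, valid for simple curves); 'count' by the number of
        input points the polyline covers.
    measure_mode
        Which candidate measures participate: 'max_only', 'max_min' or
        'max_min_median'.
    max_recursion_depth
        Cap on reduction recursion levels.
    min_subset_size
        Point sets smaller than this are approximated by their
        farthest pair only.
    gap_tol
        Maximum projected gap (pixels) allowed in the chain of points
        covering a segment for the pair to count as closed.  For 1-px
        edge maps with ~0.5 px point jitter the largest gap along a
        long edge routinely reaches 3 px, so the default leaves head
        room above that.
    dev_tol
        Deviation tolerance (pixels) when pruning redundant vertices
        after extraction.
    band_floor
        Absolute lower bound (pixels) on the collinearity band width:
        on short segments a purely relative eps-band would be narrower
        than the point jitter it must absorb.
    refine
        Relocalise final vertices by intersecting total-least-squares
        line fits of the incident edges (averages away point jitter).
    """

    eps: float = 0.02
    confidence_mode: str = "length"
    measure_mode: str = "max_min_median"
    max_recursion_depth: int = 4
    min_subset_size: int = 5
    gap_tol: float = 4.0
    dev_tol: float = 3.0
    band_floor: float = 2.0
    refine: bool = True

    def __post_init__(self):
        if self.eps < 0:
            raise ValueError("eps must be non-negative")
        if not (0.0 <= self.eps <= 0.05):
            import warnings

            warnings.warn("eps outside the recommended [0, 0.05] range", stacklevel=2)
        if self.confidence_mode not in ("length", "count"):
            raise ValueError("confidence_mode must be 'length' or 'count'")
        if self.measure_mode not in ("max_only", "max_min", "max_min_median"):
            raise ValueError("unknown measure_mode")


@dataclass
class ExtractionStats:
    """Instrumentation counters filled during extraction."""

    insertions: int = 0
    reductions: int = 0
    closures: int = 0
    max_depth: int = 0
    selected_by_measure: dict = field(
        default_factory=lambda: {m: 0 for m in Measure}
    )


def farthest_pair(P: PointSet) -> tuple[np.ndarray, np.ndarray]:
    """Pair of points of ``P`` at maximal Euclidean distance.

    Exhaustive over all pairs; ties resolved by lowest point index.
    """
    pts = P.coords if isinstance(P, PointSet) else PointSet(P).coords
    n = len(pts)
    if n < 2:
        raise ValueError("farthest_pair needs at least 2 points")
    d = cdist(pts, pts)
    i, j = np.unravel_index(int(np.argmax(d)), d.shape)
    if i > j:
        i, j = j, i
    return pts[i].copy(), pts[j].copy()


def sum_distance_scores(P: PointSet, seq: DominantSequence) -> np.ndarray:
    """Score f(p) = sum_i |p - v_i| over the sequence vertices, per point."""
    if len(seq) < 2:
        raise ValueError("sequence needs at least 2 vertices")
    pts = P.coords if isinstance(P, PointSet) else np.atleast_2d(P)
    if pts.shape[0] == 0:
        return np.empty(0)
    return cdist(pts, seq.vertices).sum(axis=1)


def balance_ratio(v, seq: DominantSequence, slot: int) -> float:
    """min/max of the candidate's distances to its slot endpoints.

    1 means perfectly balanced placement; 0 (by convention) when the
    candidate coincides with an endpoint, so degenerate insertions are
    never preferred.
    """
    a, b = seq.pair(slot)
    p = np.asarray(v, dtype=float).reshape(2)
    da = float(np.linalg.norm(p - a))
    db = float(np.linalg.norm(p - b))
    lo, hi = min(da, db), max(da, db)
    if lo < 1e-9:
        return 0.0
    return lo / hi


def best_slot(
    seq: DominantSequence,
    v,
    confidence_mode: str = "length",
    C: PointSet | None = None,
    tol: float = 0.02,
) -> tuple[int, float]:
    """Open slot where inserting ``v`` keeps the sequence most plausible.

    For the length criterion the winning slot adds the least polyline
    length (the shortest cyclic tour through the augmented vertex set
    is the simple, non-self-intersecting order); the returned
    confidence is the resulting cyclic length.  For the count
    criterion the winning slot maximises the number of points of ``C``
    covered by the augmented polyline.  Ties go to the lowest slot
    index.  Raises if every pair is closed (terminal sequence).
    """
    open_idx = seq.open_pair_indices()
    if not open_idx:
        raise ValueError("all pairs closed: terminal sequence")
    p = np.asarray(v, dtype=float).reshape(2)

    if confidence_mode == "length":
        base = confidence_length(seq)
        surpluses = []
        for i in open_idx:
            a, b = seq.pair(i)
            surpluses.append(
                float(np.linalg.norm(p - a) + np.linalg.norm(p - b)
                      - np.linalg.norm(a - b))
            )
        order = sorted(range(len(open_idx)), key=lambda j: (surpluses[j], j))
        # prefer the shortest-detour slot that keeps the ring simple:
        # a nearly-tied slot on the wrong side of a narrow neck would
        # otherwise scramble the cyclic order
        if len(seq) >= 3:
            from shapely.geometry import Polygon

            for j in order:
                ring = np.insert(seq.vertices, open_idx[j] + 1, p, axis=0)
                if Polygon(ring).is_valid:
                    return open_idx[j], float(base + surpluses[j])
        j = order[0]
        return open_idx[j], float(base + surpluses[j])

    if C is None:
        raise ValueError("confidence_mode='count' requires the point set C")
    best_i, best_conf = -1, -1
    for i in open_idx:
        conf = confidence_count(seq.with_insertion(p, i), C, tol)
        if conf > best_conf:
            best_i, best_conf = i, conf
    return best_i, float(best_conf)


def candidates(
    P: PointSet,
    seq: DominantSequence,
    measure_mode: str = "max_min_median",
    confidence_mode: str = "length",
    C: PointSet | None = None,
    tol: float = 0.02,
    exclude_radius: float = 0.0,
) -> list[CandidateInsertion]:
    """Candidate dominant points under the configured measures.

    Returns one candidate per distinct measure outcome (argmax, argmin
    and median order statistic of the sum-distance score), each with
    its best open slot, confidence and balance ratio.  ``P`` must not
    contain the current vertices; points within ``exclude_radius`` of
    an existing vertex are additionally ignored (a sample a pixel away
    from a found vertex carries no new shape information).  Empty
    ``P`` signals termination with an empty list.
    """
    pts = P.coords if isinstance(P, PointSet) else np.atleast_2d(P)
    if pts.shape[0] == 0:
        return []
    f = sum_distance_scores(P, seq)
    picks: list[tuple[Measure, int]] = [(Measure.MAX, int(np.argmax(f)))]
    if measure_mode in ("max_min", "max_min_median"):
        # the min and median order statistics are noise-prone right next
        # to an existing vertex (a 1-px neighbour of a found vertex often
        # minimises the score); keep those measures away from found
        # structure, while the argmax is left untouched
        if exclude_radius > 0:
            far = cdist(pts, seq.vertices).min(axis=1) > exclude_radius
        else:
            far = np.ones(len(pts), dtype=bool)
        if far.any():
            f_far = np.where(far, f, np.inf)
            picks.append((Measure.MIN, int(np.argmin(f_far))))
            if measure_mode == "max_min_median":
                idx_far = np.where(far)[0]
                order = idx_far[np.argsort(f[idx_far], kind="stable")]
                picks.append((Measure.MEDIAN, int(order[(len(order) - 1) // 2])))

    out: list[CandidateInsertion] = []
    seen: set[int] = set()
    for measure, idx in picks:
        if idx in seen:
            continue
        seen.add(idx)
        p = pts[idx]
        slot, conf = best_slot(seq, p, confidence_mode, C, tol)
        out.append(
            CandidateInsertion(
                point=p,
                measure=measure,
                slot=slot,
                confidence=conf,
                ratio=balance_ratio(p, seq, slot),
            )
        )
    return out


def select_candidate(cands: list[CandidateInsertion]) -> CandidateInsertion:
    """Balance-oriented selection: the candidate with the largest ratio.

    Ties are resolved by measure priority max > min > median.
    """
    if not cands:
        raise ValueError("no candidates")
    return min(cands, key=lambda c: (-c.ratio, _MEASURE_PRIORITY[c.measure]))


def _near_mask(pts: np.ndarray, a: np.ndarray, b: np.ndarray, eps: float,
               band_floor: float = 0.0) -> np.ndarray:
    """Points within the sum-distance band of segment ab."""
    length = np.linalg.norm(a - b)
    s = np.linalg.norm(pts - a, axis=1) + np.linalg.norm(pts - b, axis=1)
    return s <= length + max(eps * length, band_floor) + 1e-9


def _covers(pts: np.ndarray, a: np.ndarray, b: np.ndarray, gap_tol: float) -> bool:
    """Whether projections of ``pts`` onto ab chain-cover the segment.

    Interior gaps may not exceed ``gap_tol``; the two end gaps are
    allowed twice that, because when this pair shares a vertex with an
    already-closed pair, the neighbour's removal band legitimately
    swallows a few points just past the shared corner.
    """
    if pts.shape[0] == 0:
        return False
    d = b - a
    length = float(np.linalg.norm(d))
    t = np.clip((pts - a) @ d / (length * length), 0.0, 1.0) * length
    t.sort()
    knots = np.concatenate(([0.0], t, [length]))
    gaps = np.diff(knots)
    end_zone = 2.0 * gap_tol
    in_end_zone = (knots[:-1] < end_zone) | (knots[1:] > length - end_zone)
    allowed = np.where(in_end_zone, 2.0 * gap_tol, gap_tol)
    return bool(np.all(gaps <= allowed))


def _closed_predicate(
    a: np.ndarray, b: np.ndarray, P: PointSet, eps: float, gap_tol: float,
    band_floor: float = 0.0
) -> bool:
    pts = P.coords
    if pts.shape[0] == 0:
        return False
    near = _near_mask(pts, a, b, eps, band_floor)
    return _covers(pts[near], a, b, gap_tol)


def test_closedness(
    v, w, P: PointSet, eps: float = 0.02, gap_tol: float = 4.0,
    band_floor: float = 0.0
) -> tuple[bool, PointSet]:
    """Closedness of the pair (v, w) given point set ``P``.

    The pair is closed when the points of ``P`` inside the relative
    sum-distance band of segment vw, projected onto the segment and
    sorted, cover it without any gap larger than ``gap_tol`` pixels.
    When closed, those covering points are removed from the returned
    point set; otherwise ``P`` is returned unchanged.
    """
    a = np.asarray(v, dtype=float).reshape(2)
    b = np.asarray(w, dtype=float).reshape(2)
    if np.linalg.norm(a - b) < 1e-9:
        raise ValueError("closedness needs distinct endpoints")
    pts = P.coords
    if pts.shape[0] == 0:
        return False, P
    near = _near_mask(pts, a, b, eps, band_floor)
    if not _covers(pts[near], a, b, gap_tol):
        return False, P
    return True, PointSet(pts[~near])


#: neighbour-linking radius (pixels) for the boundary graph used in
#: geodesic subset assignment.  Consecutive points of a 1-px chain with
#: ~0.5 px jitter can land ~3.5 px apart, so 4 keeps chains connected.
_LINK_RADIUS = 4.0


def _geodesic_to_pairs(
    P: PointSet,
    seq: DominantSequence,
    open_idx: list[int],
    remaining: np.ndarray,
) -> np.ndarray | None:
    """Graph-geodesic distance from each remaining point to each open pair.

    Builds a radius graph over all of ``P`` (edge-pixel chains are
    connected at ~1 px spacing) and runs multi-source Dijkstra from each
    open pair's two endpoint vertices.  Entry [i, j] is the distance
    from remaining point i to open pair j along the boundary; inf where
    unreachable.  Returns None when the endpoints are not points of
    ``P`` (nothing to anchor the search on).
    """
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import dijkstra
    from scipy.spatial import cKDTree

    pts = P.coords
    n = len(pts)
    if n < 3:
        return None
    tree = cKDTree(pts)
    pairs = tree.query_pairs(_LINK_RADIUS, output_type="ndarray")
    if len(pairs) == 0:
        return None
    wts = np.linalg.norm(pts[pairs[:, 0]] - pts[pairs[:, 1]], axis=1)
    graph = coo_matrix(
        (np.concatenate([wts, wts]),
         (np.concatenate([pairs[:, 0], pairs[:, 1]]),
          np.concatenate([pairs[:, 1], pairs[:, 0]]))),
        shape=(n, n),
    ).tocsr()

    def vertex_row(v: np.ndarray) -> int | None:
        hit = np.where((pts == v).all(axis=1))[0]
        return int(hit[0]) if hit.size else None

    pair_rows = []
    for i in open_idx:
        a, b = seq.pair(i)
        ra, rb = vertex_row(a), vertex_row(b)
        if ra is None or rb is None:
            return None
        pair_rows.append((ra, rb))

    # map remaining points back to rows of P (same coordinate objects)
    eq = (pts[:, None, :] == remaining[None, :, :]).all(axis=2)
    rem_rows = np.argmax(eq, axis=0)
    if not eq[rem_rows, np.arange(len(remaining))].all():
        return None

    # per pair, block a small disk around every *other* sequence vertex:
    # boundary paths may not run through foreign dominant points, so a
    # point only reaches the endpoints of the arc it actually lies on
    out = np.full((len(remaining), len(open_idx)), np.inf)
    all_d = cdist(pts, seq.vertices)
    for jcol, (ra, rb) in enumerate(pair_rows):
        a, b = seq.pair(open_idx[jcol])
        other = np.ones(len(seq), dtype=bool)
        for v in (a, b):
            other &= ~np.all(np.abs(seq.vertices - v) < 1e-9, axis=1)
        blocked = (all_d[:, other] < 3.0).any(axis=1) if other.any() else \
            np.zeros(n, dtype=bool)
        blocked[ra] = blocked[rb] = False
        keep = np.where(~blocked)[0]
        pos = -np.ones(n, dtype=int)
        pos[keep] = np.arange(len(keep))
        if pos[ra] < 0 or pos[rb] < 0:
            continue
        sub = graph[keep][:, keep]
        d = dijkstra(sub, directed=False, indices=[pos[ra], pos[rb]])
        duw = d[0][pos[rb]]  # the pair's own arc length in the cut graph
        if not np.isfinite(duw):
            duw = 0.0
        dr = np.full(n, np.inf)
        # geodesic excess over the pair's own arc: zero exactly on it
        dr[keep] = d[0] + d[1] - duw
        out[:, jcol] = dr[rem_rows]
    return out


def reduce_point_set(
    P: PointSet,
    seq: DominantSequence,
    eps: float = 0.02,
    gap_tol: float = 4.0,
    skip_pair: int | None = None,
    band_floor: float = 0.0,
) -> tuple[list[tuple[PointSet, int]], PointSet]:
    """Divide-and-conquer reduction step.

    Removes every point of ``P`` lying in the band of some *closed*
    pair (those segments are already explained), drops the current
    vertices, and assigns each surviving point to the open pair
    minimising its point-segment sum distance.  Returns the per-open-
    pair subsets (pairs with no points are omitted) and the removed
    points; subsets plus removed plus vertices account for all of ``P``.

    ``skip_pair`` exempts one pair from band removal: a recursion
    child's anchor chord is closed to insertion but is not a
    point-supported boundary segment, so it must not swallow points.
    """
    pts = P.coords
    k = len(seq)
    removed_mask = np.zeros(len(pts), dtype=bool)
    # removal is more generous than the cover test: a point within twice
    # the noise floor of an explained segment is a straggler of that
    # segment, not the seed of a new subset
    for i, closed in enumerate(seq.closed):
        if closed and i != skip_pair:
            a, b = seq.pair(i)
            removed_mask |= _near_mask(pts, a, b, eps, 2.0 * band_floor)
    # current vertices never belong to a subset
    vert_mask = (
        (pts[:, None, :] == seq.vertices[None, :, :]).all(axis=2).any(axis=1)
        if len(pts)
        else np.zeros(0, dtype=bool)
    )
    keep = ~(removed_mask | vert_mask)
    remaining = pts[keep]
    open_idx = seq.open_pair_indices()
    if not open_idx or remaining.shape[0] == 0:
        return [], PointSet(pts[removed_mask | vert_mask])

    if k == 2:
        # both cyclic slots share one segment: split by side of the chord
        a, b = seq.pair(0)
        d = b - a
        rel = remaining - a
        side = d[0] * rel[:, 1] - d[1] * rel[:, 0]
        groups = {0: remaining[side >= 0], 1: remaining[side < 0]}
    else:
        # Sum distance in excess of the pair's own length (the ellipse-band
        # criterion) keeps points with the arc they lie on rather than the
        # pair with the nearest far endpoint.  Where the boundary folds
        # close to itself (a narrow neck between touching objects) spatial
        # proximity still lies, so points reachable along the pixel chain
        # are assigned by geodesic distance to the pair endpoints instead.
        excess = np.stack(
            [
                np.linalg.norm(remaining - seq.pair(i)[0], axis=1)
                + np.linalg.norm(remaining - seq.pair(i)[1], axis=1)
                - np.linalg.norm(seq.pair(i)[0] - seq.pair(i)[1])
                for i in open_idx
            ],
            axis=1,
        )
        choice = np.argmin(excess, axis=1)
        geo = _geodesic_to_pairs(P, seq, open_idx, remaining)
        if geo is not None:
            override = np.isfinite(geo).any(axis=1)
            choice[override] = np.argmin(geo[override], axis=1)
        groups = {
            open_idx[j]: remaining[choice == j] for j in range(len(open_idx))
        }

    subsets = [
        (PointSet(g), i) for i, g in sorted(groups.items()) if g.shape[0] > 0
    ]
    return subsets, PointSet(pts[removed_mask | vert_mask])


def insert(
    seq: DominantSequence,
    cand: CandidateInsertion,
    P: PointSet | None = None,
    eps: float = 0.02,
    gap_tol: float = 4.0,
    band_floor: float = 0.0,
) -> DominantSequence:
    """Insert a candidate into its slot, assigning closed tags eagerly.

    The two pairs created by the split are tested for closedness
    against ``P`` (predicate only; no points are removed here) and
    tagged accordingly; with ``P=None`` both start open.  All other
    tags are preserved.  Raises on insertion into a closed pair.
    """
    if seq.closed[cand.slot]:
        raise ValueError("cannot insert into a closed pair")
    a, b = seq.pair(cand.slot)
    if P is not None:
        tags = (
            _closed_predicate(a, cand.point, P, eps, gap_tol, band_floor),
            _closed_predicate(cand.point, b, P, eps, gap_tol, band_floor),
        )
    else:
        tags = (False, False)
    return seq.with_insertion(cand.point, cand.slot, tags)


# ---------------------------------------------------------------------------
# recursive driver
# ---------------------------------------------------------------------------


def _splice_path(
    child: DominantSequence, u: np.ndarray, w: np.ndarray
) -> tuple[np.ndarray, list[bool]]:
    """Interior vertices and pair tags of the child path joining u to w.

    The child cycle is cut at u and w; of the two directed paths from u
    to w the one with more interior vertices wins (ties: longer
    polyline, then forward orientation).  Returns the interior vertex
    block and the tags of the ``len(interior) + 1`` pairs from u to w.
    """
    k = len(child)

    def locate(p: np.ndarray) -> int:
        idx = child.index_of(p)
        if idx is not None:
            return idx
        return int(np.argmin(np.linalg.norm(child.vertices - p, axis=1)))

    iu, iw = locate(u), locate(w)
    if iu == iw:
        return np.empty((0, 2)), [child.closed[iu % k]]

    def path(forward: bool) -> tuple[list[int], list[bool]]:
        idxs, tags = [iu], []
        j = iu
        while j != iw:
            nxt = (j + 1) % k if forward else (j - 1) % k
            tags.append(child.closed[j % k] if forward else child.closed[nxt % k])
            idxs.append(nxt)
            j = nxt
        return idxs, tags

    fwd_idx, fwd_tags = path(True)
    bwd_idx, bwd_tags = path(False)

    def poly_len(idxs: list[int]) -> float:
        v = child.vertices[idxs]
        return float(np.linalg.norm(np.diff(v, axis=0), axis=1).sum())

    if len(fwd_idx) != len(bwd_idx):
        idxs, tags = (fwd_idx, fwd_tags) if len(fwd_idx) > len(bwd_idx) else (bwd_idx, bwd_tags)
    else:
        idxs, tags = (
            (fwd_idx, fwd_tags)
            if poly_len(fwd_idx) >= poly_len(bwd_idx)
            else (bwd_idx, bwd_tags)
        )
    interior = child.vertices[idxs[1:-1]]
    return interior, tags


def _splice(
    seq: DominantSequence,
    slot: int,
    interior: np.ndarray,
    tags: list[bool],
) -> DominantSequence:
    """Replace open pair ``slot`` by the path u -> interior -> w."""
    if interior.shape[0] == 0:
        seq.closed[slot] = seq.closed[slot] or tags[0]
        return seq
    # drop interior vertices colliding with existing ones (rare; exact match)
    keep_rows, kept_tags = [], [tags[0]]
    for j in range(interior.shape[0]):
        if seq.index_of(interior[j]) is None and not any(
            np.array_equal(interior[j], interior[r]) for r in keep_rows
        ):
            keep_rows.append(j)
            kept_tags.append(tags[j + 1])
        else:
            kept_tags[-1] = kept_tags[-1] and tags[j + 1]
    interior = interior[keep_rows]
    if interior.shape[0] == 0:
        seq.closed[slot] = seq.closed[slot] or kept_tags[0]
        return seq
    verts = np.concatenate(
        [seq.vertices[: slot + 1], interior, seq.vertices[slot + 1:]], axis=0
    )
    new_tags = seq.closed[:slot] + kept_tags + seq.closed[slot + 1:]
    return DominantSequence(verts, new_tags)


def _tag_open_pairs(seq: DominantSequence, P: PointSet,
                    cfg: ExtractionConfig) -> None:
    for i in seq.open_pair_indices():
        a, b = seq.pair(i)
        if _closed_predicate(a, b, P, cfg.eps, cfg.gap_tol, cfg.band_floor):
            seq.closed[i] = True


def _grow_third_point(
    P: PointSet, seq: DominantSequence, cfg: ExtractionConfig, stats: ExtractionStats
) -> DominantSequence:
    """Insert the sum-distance maximiser as 3rd vertex.

    When even the farthest-scoring point stays inside the collinearity
    band of the initial pair, the set is a 1-piece polyline (a straight
    segment) and the pair itself is the final approximation; growing a
    sliver triangle out of it would only breed spurious vertices.
    """
    avail = P.difference(seq.vertices)
    if len(avail) == 0:
        return seq
    f = sum_distance_scores(avail, seq)
    p = avail.coords[int(np.argmax(f))]
    if is_insertable(p, seq, cfg.eps, cfg.band_floor):
        _tag_open_pairs(seq, P, cfg)
        return seq
    slot, conf = best_slot(seq, p, cfg.confidence_mode, P, cfg.eps)
    cand = CandidateInsertion(
        point=p,
        measure=Measure.MAX,
        slot=slot,
        confidence=conf,
        ratio=balance_ratio(p, seq, slot),
    )
    stats.insertions += 1
    stats.selected_by_measure[Measure.MAX] += 1
    seq = insert(seq, cand, P, cfg.eps, cfg.gap_tol, cfg.band_floor)
    # the initial pair's other cyclic slot was never closedness-tested
    _tag_open_pairs(seq, P, cfg)
    return seq


def _extract(
    P: PointSet,
    cfg: ExtractionConfig,
    depth: int,
    stats: ExtractionStats,
    anchor: tuple[np.ndarray, np.ndarray] | None = None,
) -> DominantSequence:
    """Recursive driver.

    ``anchor`` is set for recursion children: the subset refines the
    boundary between the parent's open pair (u, w), so the sequence is
    initialised to exactly that pair and the reverse pair (w, u) — the
    parent's chord, which is not part of the boundary being traced —
    is born closed so nothing is ever inserted into it.
    """
    stats.max_depth = max(stats.max_depth, depth)
    if anchor is not None:
        seq = DominantSequence([anchor[0], anchor[1]], [False, True])
    else:
        v1, v2 = farthest_pair(P)
        seq = DominantSequence([v1, v2])
    if len(P) < cfg.min_subset_size:
        return seq
    seq = _grow_third_point(P, seq, cfg, stats)
    if len(seq) < 3:
        return seq

    max_iter = len(P) + 8
    for _ in range(max_iter):
        if seq.all_closed:
            return seq
        avail = P.difference(seq.vertices)
        cands = candidates(
            avail, seq, cfg.measure_mode, cfg.confidence_mode, P, cfg.eps,
            exclude_radius=cfg.dev_tol,
        )
        if not cands:
            return seq
        sel = select_candidate(cands)
        if is_insertable(sel.point, seq, cfg.eps, cfg.band_floor):
            before = confidence_length(seq)
            seq = insert(seq, sel, P, cfg.eps, cfg.gap_tol, cfg.band_floor)
            after = confidence_length(seq)
            # insertion can only lengthen the cyclic polyline
            assert after >= before - 1e-6, "polyline-length confidence decreased"
            stats.insertions += 1
            stats.selected_by_measure[sel.measure] += 1
        else:
            return _reduce_and_recurse(P, seq, cfg, depth, stats,
                                       anchored=anchor is not None)
    return seq


def _reduce_and_recurse(
    P: PointSet,
    seq: DominantSequence,
    cfg: ExtractionConfig,
    depth: int,
    stats: ExtractionStats,
    anchored: bool = False,
) -> DominantSequence:
    stats.reductions += 1
    for i in seq.open_pair_indices():
        a, b = seq.pair(i)
        if _closed_predicate(a, b, P, cfg.eps, cfg.gap_tol, cfg.band_floor):
            seq.closed[i] = True
            stats.closures += 1
    if seq.all_closed:
        return seq
    # in an anchored child the closing pair is the parent chord
    skip = len(seq) - 1 if anchored else None
    subsets, _removed = reduce_point_set(P, seq, cfg.eps, cfg.gap_tol, skip,
                                         cfg.band_floor)
    if not subsets or depth >= cfg.max_recursion_depth:
        return seq

    # splice children back, highest slot first so lower indices stay valid
    for subset, slot in sorted(subsets, key=lambda t: -t[1]):
        u, w = seq.pair(slot)
        child_pts = PointSet(np.concatenate([subset.coords, [u, w]], axis=0))
        if len(child_pts) < cfg.min_subset_size:
            continue
        if len(child_pts) >= len(P):
            continue  # no progress; avoid infinite recursion
        child = _extract(child_pts, cfg, depth + 1, stats, anchor=(u, w))
        interior, tags = _splice_path(child, u, w)
        seq = _splice(seq, slot, interior, tags)
    return seq


def _point_segment_deviation(v: np.ndarray, u: np.ndarray, w: np.ndarray) -> float:
    """Euclidean distance from v to the closed segment uw."""
    d = w - u
    denom = float(d @ d)
    if denom < 1e-18:
        return float(np.linalg.norm(v - u))
    t = np.clip((v - u) @ d / denom, 0.0, 1.0)
    return float(np.linalg.norm(v - (u + t * d)))


def simplify(seq: DominantSequence, eps: float = 0.02,
             dev_tol: float = 0.0) -> DominantSequence:
    """Drop vertices that are not genuinely dominant.

    A vertex v between cyclic neighbours u, w is redundant when
    ``|u-v| + |v-w| <= (1+eps) |u-w|`` — it lies inside the
    collinearity band of its neighbours' chord and by the
    insertability definition carries no shape information (the
    rectangle's fifth point) — or when its deviation from the segment
    uw is below ``dev_tol`` pixels (catches backtracking vertices a
    pixel or two apart, where the relative band test is powerless
    because the chord itself is short).  Most-redundant vertices go
    first, until none qualify or only three remain; a merged pair is
    tagged closed only when both removed pairs were closed.
    """
    verts = [v for v in seq.vertices]
    tags = list(seq.closed)
    while len(verts) > 3:
        k = len(verts)
        scores = []
        for i in range(k):
            u, v, w = verts[(i - 1) % k], verts[i], verts[(i + 1) % k]
            chord = np.linalg.norm(u - w)
            if chord < 1e-9:
                scores.append((0.0, -np.inf))
                continue
            excess = (np.linalg.norm(u - v) + np.linalg.norm(v - w)) / chord - 1.0
            dev = _point_segment_deviation(v, u, w)
            scores.append((min(excess - eps, dev - dev_tol), dev))
        i = int(np.argmin([s[0] for s in scores]))
        if scores[i][0] > 0:
            break
        merged = tags[(i - 1) % k] and tags[i]
        tags[(i - 1) % k] = merged
        del verts[i], tags[i]
    return DominantSequence(np.array(verts), tags)


def _dedupe_vertices(seq: DominantSequence, tol: float) -> DominantSequence:
    """Collapse vertices closer than ``tol`` to an earlier vertex.

    Two non-adjacent vertices a couple of pixels apart are always two
    discoveries of the same feature (e.g. a junction found once per
    incident arc); the later one is dropped.
    """
    verts = [v for v in seq.vertices]
    tags = list(seq.closed)
    changed = True
    while changed and len(verts) > 3:
        changed = False
        k = len(verts)
        for j in range(k - 1, 0, -1):
            d = np.linalg.norm(np.asarray(verts[:j]) - verts[j], axis=1)
            if d.min() < tol:
                merged = tags[(j - 1) % len(tags)] and tags[j]
                tags[(j - 1) % len(tags)] = merged
                del verts[j], tags[j]
                changed = True
                break
    return DominantSequence(np.array(verts), tags)


def _repair_simple(seq: DominantSequence) -> DominantSequence:
    """Restore ring simplicity by dropping the sharpest vertices.

    A valid dominant sequence traces a simple closed polygon; when a
    stray insertion leaves a self-intersection, the offending vertices
    are the spike-like ones (smallest cross angle), so those are
    removed until the ring is simple again.
    """
    from shapely.geometry import Polygon

    from .geometry import vertex_angle

    verts = [v for v in seq.vertices]
    tags = list(seq.closed)
    while len(verts) > 3 and not Polygon(np.array(verts)).is_valid:
        k = len(verts)
        angles = []
        for i in range(k):
            try:
                angles.append(
                    vertex_angle(verts[(i - 1) % k], verts[i], verts[(i + 1) % k])
                )
            except ValueError:
                angles.append(-1.0)
        i = int(np.argmin(angles))
        merged = tags[(i - 1) % k] and tags[i]
        tags[(i - 1) % k] = merged
        del verts[i], tags[i]
    return DominantSequence(np.array(verts), tags)


def refine_vertices(seq: DominantSequence, P: PointSet,
                    window: float = 12.0, max_shift: float = 6.0,
                    min_angle_cos: float = 0.97) -> DominantSequence:
    """Relocalise each vertex to the intersection of its two edge lines.

    The sum-distance argmax lands on a sampled (jittered) point near a
    corner, which carries the full point noise.  Fitting a total-least-
    squares line to the input points along each incident edge within
    ``window`` pixels of the vertex and intersecting the two lines
    averages that noise away.  A vertex is left untouched when either
    side has too few points, the lines are nearly parallel (smooth
    contour, ``min_angle_cos`` on the absolute cosine), or the
    refined position moves more than ``max_shift`` pixels.
    """
    pts = P.coords
    k = len(seq)
    out = seq.vertices.copy()
    for i in range(k):
        u, v, w = seq.vertices[(i - 1) % k], seq.vertices[i], seq.vertices[(i + 1) % k]
        local = pts[np.linalg.norm(pts - v, axis=1) <= window]
        if len(local) < 8:
            continue
        eu = (u - v) / np.linalg.norm(u - v)
        ew = (w - v) / np.linalg.norm(w - v)
        if abs(eu @ ew) > min_angle_cos:
            continue  # edges nearly collinear: intersection ill-conditioned
        rel = local - v
        tu = rel @ eu
        tw = rel @ ew
        side_u = local[(tu > tw) & (tu > 0.5)]
        side_w = local[(tw >= tu) & (tw > 0.5)]
        if len(side_u) < 4 or len(side_w) < 4:
            continue

        def tls_line(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
            mean = a.mean(axis=0)
            _, _, vt = np.linalg.svd(a - mean, full_matrices=False)
            return mean, vt[0]

        p1, d1 = tls_line(side_u)
        p2, d2 = tls_line(side_w)
        m = np.column_stack([d1, -d2])
        if abs(np.linalg.det(m)) < 1e-6:
            continue
        t = np.linalg.solve(m, p2 - p1)
        cand = p1 + t[0] * d1
        if np.linalg.norm(cand - v) <= max_shift:
            out[i] = cand
    if len(np.unique(out, axis=0)) != k:
        return seq
    return DominantSequence(out, list(seq.closed))


def extract(P, cfg: ExtractionConfig | None = None) -> DominantSequence:
    """Extract the cyclic dominant-point sequence of a point set."""
    seq, _ = extract_with_stats(P, cfg)
    return seq


def extract_with_stats(
    P, cfg: ExtractionConfig | None = None
) -> tuple[DominantSequence, ExtractionStats]:
    """Like :func:`extract` but also returns instrumentation counters."""
    if not isinstance(P, PointSet):
        P = PointSet(P)
    if len(P) < 2:
        raise ValueError("need at least 2 points")
    cfg = cfg or ExtractionConfig()
    stats = ExtractionStats()
    seq = _extract(P, cfg, 0, stats)
    if len(seq) > 3:
        seq = simplify(seq, cfg.eps, dev_tol=cfg.dev_tol)
        seq = _dedupe_vertices(seq, tol=cfg.dev_tol)
        seq = _repair_simple(seq)
        seq = simplify(seq, cfg.eps, dev_tol=cfg.dev_tol)
    if cfg.refine and len(seq) >= 3:
        # second pass: neighbour positions sharpen after the first
        seq = refine_vertices(refine_vertices(seq, P), P)
    return seq, stats
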