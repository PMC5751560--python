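"""Primitive geometric quantities for dominant-point extraction.

Coordinates follow raster conventions: x grows rightwards, y grows
downwards, pixel centers sit on integer coordinates (0-based).  All
distances are Euclidean and expressed in pixel units.

The central primitive is the *point-line-segment distance*
``|p - a| + |p - b|`` for a segment ``ab`` — the sum of distances to the
two endpoints, not the perpendicular point-line distance.  A point lies
(approximately) on a segment exactly when this sum is within a relative
tolerance of the segment length, which is the collinearity test used
throughout the extractor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, TYPE_CHECKING

import numpy as np
from scipy.spatial.distance import cdist

if TYPE_CHECKING:  # pragma: no cover
    from .sequence import DominantSequence

__all__ = [
    "Point2D",
    "PointSet",
    "Segment",
    "point_segment_sum_distance",
    "is_insertable",
    "confidence_count",
    "confidence_length",
    "fermat_point",
    "vertex_angle",
]

#: numerical slack used when comparing sum-distances against segment
#: lengths; protects exact on-segment points from round-off.
_ABS_SLACK = 1e-9

#: segments shorter than this are rejected as degenerate.
_MIN_SEGMENT_LENGTH = 1e-9


def as_point(p) -> np.ndarray:
    """Coerce ``p`` to a finite float ndarray of shape (2,)."""
    a = np.asarray(p, dtype=float)
    if a.shape != (2,):
        raise ValueError(f"expected a 2-D point, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError("point coordinates must be finite")
    return a


# Point2D is an alias: any length-2 sequence of finite floats.  Helper
# functions coerce via :func:`as_point`; arrays of points are (n, 2).
Point2D = np.ndarray


class PointSet:
    """Unordered set of 2-D points (e.g. a connected edge component).

    Exact duplicate coordinates are collapsed at construction.  The
    row order of :attr:`coords` is the deduplicated input order, which
    makes index-based tie-breaking deterministic.
    """

    __slots__ = ("coords",)

    def __init__(self, points: Iterable | np.ndarray):
        a = np.asarray(list(points) if not isinstance(points, np.ndarray) else points,
                       dtype=float)
        if a.size == 0:
            a = a.reshape(0, 2)
        if a.ndim != 2 or a.shape[1] != 2:
            raise ValueError("PointSet expects an (n, 2) array of coordinates")
        if not np.all(np.isfinite(a)):
            raise ValueError("PointSet coordinates must be finite")
        # stable dedup preserving first occurrence
        _, idx = np.unique(a, axis=0, return_index=True)
        self.coords = a[np.sort(idx)]

    def __len__(self) -> int:
        return self.coords.shape[0]

    def __iter__(self):
        return iter(self.coords)

    def __repr__(self) -> str:
        return f"PointSet(n={len(self)})"

    def difference(self, points: np.ndarray) -> "PointSet":
        """Points of self not coinciding exactly with any row of ``points``."""
        other = np.atleast_2d(np.asarray(points, dtype=float))
        if other.size == 0 or len(self) == 0:
            return PointSet(self.coords)
        eq = (self.coords[:, None, :] == other[None, :, :]).all(axis=2).any(axis=1)
        return PointSet(self.coords[~eq])


@dataclass(frozen=True)
class Segment:
    """A line segment with distinct endpoints."""

    a: np.ndarray
    b: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "a", as_point(self.a))
        object.__setattr__(self, "b", as_point(self.b))
        if self.length < _MIN_SEGMENT_LENGTH:
            raise ValueError("degenerate segment: endpoints coincide")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.a - self.b))


def point_segment_sum_distance(p, s: Segment) -> float:
    """Sum of distances from ``p`` to both endpoints of ``s``.

    Always >= the segment length (triangle inequality), with equality
    exactly when ``p`` lies on the closed segment.
    """
    q = as_point(p)
    return float(np.linalg.norm(q - s.a) + np.linalg.norm(q - s.b))


def _pair_sum_distances(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorised ``|p-a| + |p-b|`` for an (n, 2) array of points."""
    pts = np.atleast_2d(points)
    return (np.linalg.norm(pts - a, axis=1) + np.linalg.norm(pts - b, axis=1))


def is_insertable(p, seq: "DominantSequence", eps: float = 0.02,
                  band_floor: float = 0.0) -> bool:
    """Whether ``p`` is within the relative tolerance band of some open pair.

    ``p`` is insertable when, for at least one *open* consecutive pair
    ``(v_i, v_{i+1})`` of the cyclic sequence,

        |p - v_i| + |p - v_{i+1}|  <=  |v_i - v_{i+1}| + max(eps |v_i - v_{i+1}|, band_floor),

    i.e. ``p`` is nearly collinear with (and between) the pair.  Pairs
    tagged closed are excluded: no insertion is allowed there.
    ``band_floor`` (pixels) keeps the band wider than the point noise
    on short segments, where a purely relative tolerance would be
    tighter than the jitter it is meant to absorb.
    """
    if eps < 0:
        raise ValueError("eps must be non-negative")
    if len(seq) < 2:
        raise ValueError("sequence needs at least 2 vertices")
    q = as_point(p)
    for i in seq.open_pair_indices():
        a, b = seq.pair(i)
        length = np.linalg.norm(a - b)
        slack = max(eps * length, band_floor)
        if np.linalg.norm(q - a) + np.linalg.norm(q - b) <= length + slack + _ABS_SLACK:
            return True
    return False


def confidence_count(seq: "DominantSequence", C: PointSet, tol: float = 0.02) -> int:
    """Number of points of ``C`` lying on some polyline edge of ``seq``.

    "Lying on" an edge ``(a, b)`` means the point-line-segment distance
    is within ``(1 + tol)`` of the edge length.  This is the
    cardinality-based confidence of a sequence: how many points of the
    component the polyline explains.
    """
    if len(seq) < 2:
        raise ValueError("sequence needs at least 2 vertices")
    if len(C) == 0:
        return 0
    pts = C.coords
    on_any = np.zeros(len(C), dtype=bool)
    for i in range(len(seq)):
        a, b = seq.pair(i)
        length = np.linalg.norm(a - b)
        if length < _MIN_SEGMENT_LENGTH:
            continue
        on_any |= _pair_sum_distances(pts, a, b) <= (1.0 + tol) * length + _ABS_SLACK
    return int(on_any.sum())


def confidence_length(seq: "DominantSequence") -> float:
    """Total length of the cyclic polyline through the sequence.

    Includes the closing pair; for two vertices this is twice the
    segment length (out and back).
    """
    if len(seq) < 2:
        raise ValueError("sequence needs at least 2 vertices")
    v = seq.vertices
    return float(np.linalg.norm(v - np.roll(v, -1, axis=0), axis=1).sum())


def _angle_at(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Interior angle of triangle abc at vertex a."""
    u = b - a
    w = c - a
    cosang = np.dot(u, w) / (np.linalg.norm(u) * np.linalg.norm(w))
    return float(np.arccos(np.clip(cosang, -1.0, 1.0)))


def fermat_point(a, b, c) -> np.ndarray:
    """The plane point minimising total distance to triangle vertices a, b, c.

    Uses the classical equilateral-triangle construction: erect an
    equilateral triangle outward on each side and join its apex to the
    opposite vertex; the three joins meet at the Fermat point.  When an
    interior angle reaches 120 degrees the minimiser degenerates to that
    vertex.  Collinear inputs are rejected.
    """
    pa, pb, pc = as_point(a), as_point(b), as_point(c)
    d1, d2 = pb - pa, pc - pa
    area2 = d1[0] * d2[1] - d1[1] * d2[0]
    if abs(area2) < 1e-12:
        raise ValueError("fermat_point requires non-collinear points")
    two_thirds_pi = 2.0 * np.pi / 3.0
    for v, u, w in ((pa, pb, pc), (pb, pc, pa), (pc, pa, pb)):
        if _angle_at(v, u, w) >= two_thirds_pi - 1e-12:
            return v.copy()

    def outward_apex(u: np.ndarray, w: np.ndarray, opp: np.ndarray) -> np.ndarray:
        # apex of the equilateral triangle on side uw, on the far side from opp
        mid = 0.5 * (u + w)
        d = w - u
        n = np.array([-d[1], d[0]])  # normal to uw
        h = (np.sqrt(3.0) / 2.0) * n
        apex = mid + h
        if np.dot(apex - mid, opp - mid) > 0:
            apex = mid - h
        return apex

    # lines: a -> apex(bc), b -> apex(ca); solve for intersection
    p1, d1 = pa, outward_apex(pb, pc, pa) - pa
    p2, d2 = pb, outward_apex(pc, pa, pb) - pb
    m = np.column_stack([d1, -d2])
    t = np.linalg.solve(m, p2 - p1)
    return p1 + t[0] * d1


def vertex_angle(v_prev, v, v_next) -> float:
    """Cross angle at ``v`` between directions to its two neighbours.

    Returns ``arccos`` of the normalised dot product of ``v_prev - v``
    and ``v_next - v``; in [0, pi].  pi means the three points are
    collinear with ``v`` in the middle; small values mean a sharp spike.
    """
    p, q, r = as_point(v_prev), as_point(v), as_point(v_next)
    u = p - q
    w = r - q
    nu, nw = np.linalg.norm(u), np.linalg.norm(w)
    if nu < _MIN_SEGMENT_LENGTH or nw < _MIN_SEGMENT_LENGTH:
        raise ValueError("vertex_angle requires distinct neighbouring points")
    return float(np.arccos(np.clip(np.dot(u, w) / (nu * nw), -1.0, 1.0)))
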