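"""Geometrically ordered dominant-point sequences with closed tags.

A :class:`DominantSequence` is a cyclic polyline through k dominant
points.  Consecutive pair i is ``(vertices[i], vertices[(i+1) % k])``;
the closing pair wraps around, so a k-vertex sequence always has k
pairs (a 2-vertex sequence has two slots on the same segment, one per
traversal direction).  Each pair carries a boolean *closed* tag: a
closed pair is already well covered by input points and admits no
further insertion between its endpoints.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["DominantSequence", "Measure", "CandidateInsertion"]


class Measure(enum.Enum):
    """Which sum-distance order statistic produced a candidate."""

    MAX = "max"
    MIN = "min"
    MEDIAN = "median"


class DominantSequence:
    """Ordered dominant points plus per-pair closed tags."""

    __slots__ = ("vertices", "closed")

    def __init__(self, vertices, closed: Sequence[bool] | None = None):
        v = np.asarray(vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 2:
            raise ValueError("DominantSequence needs an (k>=2, 2) vertex array")
        if not np.all(np.isfinite(v)):
            raise ValueError("vertices must be finite")
        if len(np.unique(v, axis=0)) != len(v):
            raise ValueError("vertices must be distinct")
        self.vertices = v
        if closed is None:
            closed = [False] * len(v)
        closed = list(bool(c) for c in closed)
        if len(closed) != len(v):
            raise ValueError("need one closed tag per consecutive pair")
        self.closed = closed

    def __len__(self) -> int:
        return self.vertices.shape[0]

    def __repr__(self) -> str:
        tags = "".join("1" if c else "0" for c in self.closed)
        return f"DominantSequence(k={len(self)}, closed={tags})"

    def pair(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        """Endpoints of consecutive pair i (cyclic)."""
        k = len(self)
        return self.vertices[i % k], self.vertices[(i + 1) % k]

    def open_pair_indices(self) -> list[int]:
        return [i for i, c in enumerate(self.closed) if not c]

    @property
    def all_closed(self) -> bool:
        return all(self.closed)

    def copy(self) -> "DominantSequence":
        return DominantSequence(self.vertices.copy(), list(self.closed))

    def with_insertion(self, point, slot: int,
                       new_tags: tuple[bool, bool] = (False, False)) -> "DominantSequence":
        """New sequence with ``point`` inserted between pair ``slot``.

        The split creates pairs ``(v_slot, point)`` and
        ``(point, v_slot+1)`` which receive ``new_tags``; all other tags
        are preserved.
        """
        k = len(self)
        if not (0 <= slot < k):
            raise IndexError("slot out of range")
        if self.closed[slot]:
            raise ValueError("cannot insert into a closed pair")
        p = np.asarray(point, dtype=float).reshape(2)
        verts = np.insert(self.vertices, slot + 1, p, axis=0)
        tags = self.closed[: slot] + [bool(new_tags[0]), bool(new_tags[1])] + self.closed[slot + 1:]
        return DominantSequence(verts, tags)

    def index_of(self, point, atol: float = 1e-9) -> int | None:
        """Index of the vertex coinciding with ``point``, or None."""
        p = np.asarray(point, dtype=float).reshape(2)
        hits = np.where(np.all(np.abs(self.vertices - p) <= atol, axis=1))[0]
        return int(hits[0]) if hits.size else None

    # --- serialization -------------------------------------------------
    def to_frame(self):
        """CSV-ready table: order, x, y, closed_next."""
        import pandas as pd

        return pd.DataFrame(
            {
                "order": np.arange(len(self)),
                "x": self.vertices[:, 0],
                "y": self.vertices[:, 1],
                "closed_next": np.asarray(self.closed, dtype=int),
            }
        )

    @classmethod
    def from_frame(cls, df) -> "DominantSequence":
        df = df.sort_values("order")
        return cls(df[["x", "y"]].to_numpy(dtype=float),
                   df["closed_next"].astype(bool).tolist())


@dataclass
class CandidateInsertion:
    """A prospective dominant point with its placement bookkeeping.

    ``ratio`` is the balance ratio min/max of the distances from the
    candidate to the two endpoints of its chosen slot; in [0, 1], larger
    meaning a more balanced (and preferred) placement.
    """

    point: np.ndarray
    measure: Measure
    slot: int
    confidence: float
    ratio: float

    def __post_init__(self):
        self.point = np.asarray(self.point, dtype=float).reshape(2)
        if not (0.0 <= self.ratio <= 1.0 + 1e-12):
            raise ValueError("balance ratio must lie in [0, 1]")
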