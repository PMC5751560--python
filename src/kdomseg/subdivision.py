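"""Sequence subdivision: splitting touching objects at nonsmooth vertices.

Two smooth closed contours that touch merge into a single concave
outline whose junction vertices have *acute* cross angles, whereas the
inflection points of a genuinely concave single object (a bean-shaped
embryo, say) keep obtuse angles.  Thresholding the vertex angle of a
dominant-point sequence therefore separates the two situations: cut
the cycle at every acute vertex and each resulting subsequence traces
one object's boundary arc.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import vertex_angle
from .sequence import DominantSequence

__all__ = [
    "LabeledSequence",
    "Subsequence",
    "label_vertices",
    "split",
    "longest_smooth_subsequence",
]


@dataclass
class LabeledSequence:
    """A dominant sequence with per-vertex smooth/nonsmooth labels."""

    seq: DominantSequence
    nonsmooth: np.ndarray  # bool per vertex
    angles: np.ndarray  # radians per vertex

    def __post_init__(self):
        if len(self.nonsmooth) != len(self.seq) or len(self.angles) != len(self.seq):
            raise ValueError("one label and angle per vertex required")


@dataclass
class Subsequence:
    """A contiguous cyclic run of a parent sequence's vertices."""

    vertices: np.ndarray
    parent_indices: list[int]
    cyclic: bool = False  # True when it is the whole uncut cycle

    def __len__(self) -> int:
        return self.vertices.shape[0]

    @property
    def length(self) -> float:
        """Polyline length along the run (closing edge included if cyclic)."""
        v = self.vertices
        if len(v) < 2:
            return 0.0
        d = np.linalg.norm(np.diff(v, axis=0), axis=1).sum()
        if self.cyclic:
            d += np.linalg.norm(v[-1] - v[0])
        return float(d)


def label_vertices(
    seq: DominantSequence, angle_threshold: float = np.pi / 2
) -> LabeledSequence:
    """Label each vertex smooth or nonsmooth by its cross angle.

    A vertex is nonsmooth when the angle between the directions to its
    cyclic neighbours is strictly below ``angle_threshold`` (default
    90 degrees: acute = junction between touching objects, obtuse =
    smooth boundary or inflection).
    """
    k = len(seq)
    if k < 3:
        raise ValueError("labelling needs at least 3 vertices")
    v = seq.vertices
    angles = np.array(
        [vertex_angle(v[(i - 1) % k], v[i], v[(i + 1) % k]) for i in range(k)]
    )
    return LabeledSequence(seq=seq, nonsmooth=angles < angle_threshold, angles=angles)


def split(labeled: LabeledSequence) -> list[Subsequence]:
    """Cut the cyclic sequence at every nonsmooth vertex.

    Each nonsmooth vertex terminates two adjacent subsequences (it is
    shared by both).  With no nonsmooth vertex the whole cycle is
    returned as a single cyclic subsequence.
    """
    k = len(labeled.seq)
    cuts = [i for i in range(k) if labeled.nonsmooth[i]]
    v = labeled.seq.vertices
    if not cuts:
        return [Subsequence(v.copy(), list(range(k)), cyclic=True)]
    out: list[Subsequence] = []
    m = len(cuts)
    for c in range(m):
        start = cuts[c]
        stop = cuts[(c + 1) % m]
        idxs = [start]
        j = start
        while j != stop:
            j = (j + 1) % k
            idxs.append(j)
        if len(idxs) < 2:  # single cut: the run is the whole cycle back to itself
            idxs = list(range(start, k)) + list(range(0, start + 1))
        out.append(Subsequence(v[idxs].copy(), idxs))
    return out


def longest_smooth_subsequence(labeled: LabeledSequence) -> Subsequence:
    """The subsequence with the greatest polyline length.

    Ties resolve to the earliest subsequence in cut order.  For a
    fully smooth sequence this is the whole cycle.
    """
    subs = split(labeled)
    best = subs[0]
    for s in subs[1:]:
        if s.length > best.length + 1e-12:
            best = s
    return best
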