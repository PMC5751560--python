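import numpy as np
import pytest

from kdomseg.geometry import PointSet
from kdomseg.sequence import DominantSequence


@pytest.fixture
def unit_square_seq() -> DominantSequence:
    return DominantSequence([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])


@pytest.fixture
def rectangle_points() -> tuple[PointSet, np.ndarray]:
    """Exact 100x60 rectangle boundary sampled at 1-px spacing."""
    corners = np.array([[0.0, 0.0], [100.0, 0.0], [100.0, 60.0], [0.0, 60.0]])
    pts = []
    for i in range(4):
        a, b = corners[i], corners[(i + 1) % 4]
        n = int(np.linalg.norm(b - a))
        t = np.arange(n)[:, None] / n
        pts.append(a * (1 - t) + b * t)
    return PointSet(np.concatenate(pts)), corners


def brute_force_farthest(pts: np.ndarray) -> tuple[int, int]:
    """Independent O(n^2) scan via an explicit squared-distance matrix."""
    dx = pts[:, 0][:, None] - pts[:, 0][None, :]
    dy = pts[:, 1][:, None] - pts[:, 1][None, :]
    d2 = dx * dx + dy * dy
    i, j = np.unravel_index(int(np.argmax(d2)), d2.shape)
    return (i, j) if i < j else (j, i)


def brute_force_scores(pts: np.ndarray, verts: np.ndarray) -> np.ndarray:
    """Independent score accumulation, one vertex at a time."""
    out = np.zeros(len(pts))
    for v in verts:
        out += np.hypot(pts[:, 0] - v[0], pts[:, 1] - v[1])
    return out


def fermat_grid_oracle(a, b, c, step: float = 1e-3) -> np.ndarray:
    """Brute-force grid minimiser of the total vertex distance.

    Scans the bounding box at ``step``, then re-scans a small window
    around the best cell at step/20 — the objective is nearly flat
    near a 120-degree vertex, so the coarse cell centre alone can sit
    a couple of grid cells from the true minimiser.
    """
    tri = np.array([a, b, c], dtype=float)

    def scan(lo, hi, h):
        xs = np.arange(lo[0], hi[0] + h, h)
        ys = np.arange(lo[1], hi[1] + h, h)
        gx, gy = np.meshgrid(xs, ys)
        total = np.zeros_like(gx)
        for v in tri:
            total += np.hypot(gx - v[0], gy - v[1])
        i, j = np.unravel_index(int(np.argmin(total)), total.shape)
        return np.array([gx[i, j], gy[i, j]])

    best = scan(tri.min(axis=0), tri.max(axis=0), step)
    return scan(best - 2 * step, best + 2 * step, step / 20.0)
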