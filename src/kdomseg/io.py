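"""Plain-text serialisation: point sets, sequences, manifests."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import PointSet
from .sequence import DominantSequence
from .subdivision import Subsequence

__all__ = [
    "read_points",
    "write_points",
    "read_sequence",
    "write_sequence",
    "write_subsequences",
    "read_manifest",
]


def read_points(path) -> PointSet:
    """Point set from CSV with header ``x,y``, one point per row."""
    df = pd.read_csv(path)
    return PointSet(df[["x", "y"]].to_numpy(dtype=float))


def write_points(P: PointSet, path) -> None:
    pd.DataFrame(P.coords, columns=["x", "y"]).to_csv(path, index=False)


def write_sequence(seq: DominantSequence, path) -> None:
    """Columns order, x, y, closed_next (tag of the pair starting here)."""
    seq.to_frame().to_csv(path, index=False)


def read_sequence(path) -> DominantSequence:
    return DominantSequence.from_frame(pd.read_csv(path))


def write_subsequences(subs: list[Subsequence], path) -> None:
    """Same layout as a sequence CSV plus a ``component_id`` column."""
    frames = []
    for i, s in enumerate(subs):
        frames.append(
            pd.DataFrame(
                {
                    "component_id": i,
                    "order": np.arange(len(s)),
                    "x": s.vertices[:, 0],
                    "y": s.vertices[:, 1],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_manifest(path) -> list[tuple[str, str, list[str]]]:
    """Evaluation manifest: image, truth_mask_1[, truth_mask_2] per row.

    Paths are resolved relative to the manifest location.
    """
    base = Path(path).parent
    df = pd.read_csv(path)
    mask_cols = [c for c in df.columns if c.startswith("truth_mask")]
    out = []
    for _, row in df.iterrows():
        masks = [str(base / row[c]) for c in mask_cols
                 if isinstance(row[c], str) and row[c]]
        out.append((str(row["image"]), str(base / row["image"]), masks))
    return out
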