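"""Beam back-projection: (fragment track, beam line) pairs -> vertex cloud.

Each correlated pair is solved with the two-line point-of-closest-approach
(PCA) least-squares solver.  No miss-distance cut is applied by default and
the finite beam spot size is deliberately not deconvolved: the downstream
markers (depth profile, Z50, lateral means) absorb both.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import pca_batch

__all__ = ["VertexCloud", "reconstruct_vertices"]

VERTEX_COLS = ["event_id", "x", "y", "z", "miss"]


@dataclass
class VertexCloud:
    """Reconstructed vertices plus provenance.

    ``frame`` columns: event_id, x, y, z, miss (mm).  ``n_pairs`` is the
    number of input pairs; ``n_degenerate`` the near-parallel pairs that
    were excluded (counted, never silently dropped), so
    ``len(frame) + n_degenerate + n_cut == n_pairs``.
    """

    frame: pd.DataFrame
    n_pairs: int = 0
    n_degenerate: int = 0
    n_cut: int = 0
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.frame)

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            for k, v in self.metadata.items():
                fh.write(f"# {k}: {v}\n")
            self.frame.to_csv(fh, sep="\t", index=False, float_format="%.6f")
        return path

    @classmethod
    def from_tsv(cls, path: str | Path) -> "VertexCloud":
        path = Path(path)
        meta: dict[str, str] = {}
        n_meta = 0
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                n_meta += 1
                body = line[1:].strip()
                if ":" in body:
                    k, v = body.split(":", 1)
                    meta[k.strip()] = v.strip()
        frame = pd.read_csv(path, sep="\t", skiprows=n_meta)
        return cls(
            frame=frame,
            n_pairs=int(meta.get("n_pairs", len(frame))),
            n_degenerate=int(meta.get("n_degenerate", 0)),
            n_cut=int(meta.get("n_cut", 0)),
            metadata=meta,
        )


def reconstruct_vertices(
    paired: pd.DataFrame,
    parallel_tol: float = 1e-6,
    miss_cut: float | None = None,
    metadata: dict | None = None,
) -> VertexCloud:
    """Solve the PCA for every (track, beam) pair.

    ``paired`` is the output of :func:`ivims.tracks.correlate_with_beam`:
    track anchor (fx, fy, fz), unit direction (dx, dy, dz) and the SPM beam
    anchor (beam_x, beam_y).  The beam line runs along +Z.  ``miss_cut``
    optionally drops vertices whose miss distance exceeds the cut (off by
    default).  The result is order-independent: it is the same set of
    vertices for any permutation of the input pairs.
    """
    n = len(paired)
    meta = dict(metadata or {})
    meta.update({"parallel_tol": parallel_tol, "miss_cut": miss_cut, "n_pairs": n})
    if n == 0:
        frame = pd.DataFrame({c: pd.Series(dtype=float) for c in VERTEX_COLS}).astype(
            {"event_id": "int64"}
        )
        return VertexCloud(frame=frame, n_pairs=0, metadata=meta)

    a1 = paired[["fx", "fy", "fz"]].to_numpy(dtype=float)
    d1 = paired[["dx", "dy", "dz"]].to_numpy(dtype=float)
    a2 = np.column_stack(
        [
            paired["beam_x"].to_numpy(dtype=float),
            paired["beam_y"].to_numpy(dtype=float),
            np.zeros(n),
        ]
    )
    d2 = np.tile([0.0, 0.0, 1.0], (n, 1))

    pts, miss, ok = pca_batch(a1, d1, a2, d2, parallel_tol=parallel_tol)
    n_degenerate = int((~ok).sum())

    keep = ok
    n_cut = 0
    if miss_cut is not None:
        cut = ok & (miss > miss_cut)
        n_cut = int(cut.sum())
        keep = ok & ~cut

    frame = pd.DataFrame(
        {
            "event_id": paired["event_id"].to_numpy(dtype=np.int64)[keep],
            "x": pts[keep, 0],
            "y": pts[keep, 1],
            "z": pts[keep, 2],
            "miss": miss[keep],
        }
    )
    meta.update({"n_degenerate": n_degenerate, "n_cut": n_cut, "n_vertices": len(frame)})
    return VertexCloud(
        frame=frame, n_pairs=n, n_degenerate=n_degenerate, n_cut=n_cut, metadata=meta
    )
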