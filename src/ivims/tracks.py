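"""Event-by-event coincidence logic: pixel hits -> fragment tracks -> beam pairs.

A fragment track requires exactly one front-plane and one back-plane hit
sharing an acquisition event ID within a symmetric timing gate |dt| <= gate.
Events with two or more hits on either plane are pile-up and are rejected
outright (no best-pair selection): multiplicity leaves the pairing ambiguous
at the precision this reconstruction targets.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = [
    "CoincidenceStats",
    "build_tracks",
    "correlate_with_beam",
    "interstack_coincidence",
    "TRACK_COLS",
]

DEFAULT_GATE_NS = 10.0

TRACK_COLS = [
    "event_id",
    "t_front",
    "t_back",
    "fx",
    "fy",
    "fz",
    "bx",
    "by",
    "bz",
    "dx",
    "dy",
    "dz",
]


@dataclass
class CoincidenceStats:
    """Bookkeeping for one stack's event building.

    ``matched + pileup_rejected + front_only`` partitions the set of events
    that registered at least one front-plane hit.  ``back_only`` events never
    touched the front plane.  ``degenerate`` is filled downstream by the
    vertex reconstruction (near-parallel line pairs).
    """

    front_events: int = 0
    back_events: int = 0
    matched: int = 0
    pileup_rejected: int = 0
    front_only: int = 0
    back_only: int = 0
    degenerate: int = 0

    @property
    def intrastack_efficiency(self) -> float:
        """Matched tracks per front-registered event."""
        return self.matched / self.front_events if self.front_events else float("nan")

    def as_dict(self) -> dict:
        d = asdict(self)
        d["intrastack_efficiency"] = self.intrastack_efficiency
        return d


def _require_sorted(df: pd.DataFrame, name: str) -> None:
    if not df.empty and not df["event_id"].is_monotonic_increasing:
        raise ValueError(f"{name} hit stream must be sorted by event_id")


def build_tracks(
    front: pd.DataFrame, back: pd.DataFrame, gate: float = DEFAULT_GATE_NS
) -> tuple[pd.DataFrame, CoincidenceStats]:
    """Pair front/back hits into straight-line fragment tracks.

    ``front``/``back`` are list-mode hit frames (columns event_id, t, x, y,
    z at least) for the two planes of one stack, sorted by event_id.
    Returns the track table and the coincidence statistics.  Track
    directions point from the front to the back plane, i.e. with a positive
    component along the stack axis.
    """
    _require_sorted(front, "front")
    _require_sorted(back, "back")

    stats = CoincidenceStats()
    f_counts = front.groupby("event_id").size() if not front.empty else pd.Series(dtype=int)
    b_counts = back.groupby("event_id").size() if not back.empty else pd.Series(dtype=int)
    stats.front_events = int(len(f_counts))
    stats.back_events = int(len(b_counts))

    f_multi = set(f_counts.index[f_counts > 1])
    b_multi = set(b_counts.index[b_counts > 1])
    pileup_events = f_multi | b_multi
    front_ids = set(f_counts.index)
    stats.pileup_rejected = int(len(pileup_events & front_ids))
    stats.back_only = int(len(set(b_counts.index) - front_ids))

    f1 = front[~front["event_id"].isin(pileup_events)]
    b1 = back[~back["event_id"].isin(pileup_events)]
    pairs = f1.merge(b1, on="event_id", suffixes=("_f", "_b"))
    if not pairs.empty:
        pairs = pairs[(pairs["t_f"] - pairs["t_b"]).abs() <= gate]

    if pairs.empty:
        tracks = pd.DataFrame({c: pd.Series(dtype=float) for c in TRACK_COLS}).astype(
            {"event_id": "int64", "t_front": "int64", "t_back": "int64"}
        )
    else:
        d = pairs[["x_b", "y_b", "z_b"]].to_numpy() - pairs[["x_f", "y_f", "z_f"]].to_numpy()
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        tracks = pd.DataFrame(
            {
                "event_id": pairs["event_id"].to_numpy(),
                "t_front": pairs["t_f"].to_numpy(),
                "t_back": pairs["t_b"].to_numpy(),
                "fx": pairs["x_f"].to_numpy(),
                "fy": pairs["y_f"].to_numpy(),
                "fz": pairs["z_f"].to_numpy(),
                "bx": pairs["x_b"].to_numpy(),
                "by": pairs["y_b"].to_numpy(),
                "bz": pairs["z_b"].to_numpy(),
                "dx": d[:, 0],
                "dy": d[:, 1],
                "dz": d[:, 2],
            }
        )
    stats.matched = int(len(tracks))
    stats.front_only = stats.front_events - stats.matched - stats.pileup_rejected
    return tracks, stats


def correlate_with_beam(
    tracks: pd.DataFrame, spm: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Inner-join tracks with the SPM beam stream on event_id.

    The beam line per event is the SPM (x, y) anchor with a +Z direction
    (beam divergence is ignored).  Tracks without an SPM record are dropped
    and counted; events with duplicate SPM records are dropped and counted.
    Returns the paired table (track columns + beam_x, beam_y) and a dict of
    drop counters.
    """
    _require_sorted(tracks, "tracks")
    spm_counts = spm.groupby("event_id").size() if not spm.empty else pd.Series(dtype=int)
    dup_ids = set(spm_counts.index[spm_counts > 1])
    n_dup_dropped = int(tracks["event_id"].isin(dup_ids).sum()) if not tracks.empty else 0

    spm1 = spm[~spm["event_id"].isin(dup_ids)][["event_id", "x", "y"]].rename(
        columns={"x": "beam_x", "y": "beam_y"}
    )
    paired = tracks.merge(spm1, on="event_id", how="inner")
    counters = {
        "pairs": int(len(paired)),
        "tracks_without_spm": int(len(tracks)) - int(len(paired)) - n_dup_dropped,
        "duplicate_spm_dropped": n_dup_dropped,
    }
    return paired, counters


def interstack_coincidence(
    tracks_a: pd.DataFrame | None, tracks_b: pd.DataFrame | None, gate: float = DEFAULT_GATE_NS
) -> tuple[np.ndarray, float]:
    """Events with one validated track in each of two stacks within the gate.

    Returns the coincident event ids and the interstack efficiency
    (coincidences per stack-A track).  Raises on single-stack data.
    """
    if tracks_a is None or tracks_b is None:
        raise ValueError("interstack coincidence requires tracks from two stacks")
    m = tracks_a[["event_id", "t_front"]].merge(
        tracks_b[["event_id", "t_front"]], on="event_id", suffixes=("_a", "_b")
    )
    if not m.empty:
        m = m[(m["t_front_a"] - m["t_front_b"]).abs() <= gate]
    ids = m["event_id"].to_numpy(dtype=np.int64)
    eff = len(ids) / len(tracks_a) if len(tracks_a) else float("nan")
    return ids, eff
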