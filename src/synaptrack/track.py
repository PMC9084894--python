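"""Frame-to-frame trajectory linking by minimal-cost bipartite assignment.

Localizations in consecutive frames are linked one-to-one by solving the
assignment problem on the squared-displacement cost matrix, gated at a maximum
per-frame displacement ``r_max``.  This deterministic Hungarian solve minimizes
the same total cost that stochastic annealing-based trackers target, which
makes it directly checkable against exhaustive enumeration on small instances.
Unmatched localizations open new tracks; unmatched track heads terminate, or
persist for up to ``allow_gaps`` missed frames with the gate widened
proportionally.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

__all__ = ["TrackingParams", "Track", "link_localizations", "filter_tracks",
           "tracks_to_table", "tracks_from_table"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrackingParams:
    """Linking parameters: gate radius (µm per frame interval) and gap policy."""

    r_max: float = 0.5
    allow_gaps: int = 0

    def __post_init__(self) -> None:
        if self.r_max <= 0:
            raise ValueError("r_max must be > 0")
        if self.allow_gaps < 0:
            raise ValueError("allow_gaps must be >= 0")


@dataclass
class Track:
    """One molecule's trajectory: strictly increasing frames with positions."""

    track_id: int
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    intensity: np.ndarray = field(default=None)  # type: ignore[assignment]
    true_ids: np.ndarray = field(default=None)   # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.intensity is None:
            self.intensity = np.ones_like(self.x)
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("track frames must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def positions(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


def link_localizations(locs: pd.DataFrame, params: TrackingParams = TrackingParams()) -> list[Track]:
    """Link a localization table into trajectories.

    For each frame, active track heads (last seen within ``allow_gaps + 1``
    frames) are assigned to the frame's localizations by a Hungarian solve on
    squared displacements, gated at ``r_max * (gap + 1)``.  Rows are
    deduplicated on (frame, x, y) with a warning; within-frame processing
    order is canonicalized so the result is invariant to input row order.
    """
    required = {"frame", "x_um", "y_um"}
    missing = required - set(locs.columns)
    if missing:
        raise ValueError(f"localization table missing columns: {sorted(missing)}")
    n0 = len(locs)
    locs = locs.drop_duplicates(subset=["frame", "x_um", "y_um"])
    if len(locs) < n0:
        warnings.warn(f"dropped {n0 - len(locs)} duplicate (frame, x, y) localizations")
    locs = locs.sort_values(["frame", "x_um", "y_um"], kind="stable")

    has_int = "intensity" in locs.columns
    has_id = "id" in locs.columns

    # active heads: dict track_index -> (last_frame, x, y)
    tracks: list[dict] = []
    active: list[int] = []

    for frame, group in locs.groupby("frame", sort=True):
        frame = int(frame)
        pts = group[["x_um", "y_um"]].to_numpy(dtype=float)
        inten = group["intensity"].to_numpy(dtype=float) if has_int else np.ones(len(group))
        tid = group["id"].to_numpy() if has_id else np.full(len(group), -1)

        # retire heads that fell outside the gap window
        active = [k for k in active if frame - tracks[k]["last_frame"] <= params.allow_gaps + 1]

        assigned_heads: set[int] = set()
        assigned_pts: set[int] = set()
        if active and len(pts):
            heads_xy = np.array([[tracks[k]["x"][-1], tracks[k]["y"][-1]] for k in active])
            gaps = np.array([frame - tracks[k]["last_frame"] for k in active])
            cost = cdist(heads_xy, pts, metric="sqeuclidean")
            gate = (params.r_max * gaps) ** 2
            feasible = cost <= gate[:, None]
            if feasible.any():
                big = cost.max() + 1.0
                padded = np.where(feasible, cost, big * (1.0 + cost.shape[0] + cost.shape[1]))
                rows, cols = linear_sum_assignment(padded)
                for r, c in zip(rows, cols):
                    if not feasible[r, c]:
                        continue
                    k = active[r]
                    tracks[k]["frames"].append(frame)
                    tracks[k]["x"].append(pts[c, 0])
                    tracks[k]["y"].append(pts[c, 1])
                    tracks[k]["intensity"].append(inten[c])
                    tracks[k]["true_ids"].append(tid[c])
                    tracks[k]["last_frame"] = frame
                    assigned_heads.add(k)
                    assigned_pts.add(c)

        for c in range(len(pts)):
            if c in assigned_pts:
                continue
            tracks.append({
                "frames": [frame], "x": [pts[c, 0]], "y": [pts[c, 1]],
                "intensity": [inten[c]], "true_ids": [tid[c]], "last_frame": frame,
            })
            active.append(len(tracks) - 1)

    return [
        Track(i, t["frames"], t["x"], t["y"], np.asarray(t["intensity"]),
              np.asarray(t["true_ids"]))
        for i, t in enumerate(tracks)
    ]


def filter_tracks(tracks: list[Track], L_min: int = 10) -> list[Track]:
    """Keep only tracks with at least ``L_min`` localizations."""
    if L_min < 1:
        raise ValueError("L_min must be >= 1")
    kept = [t for t in tracks if len(t) >= L_min]
    logger.info("filter_tracks: kept %d / %d tracks (L_min=%d)", len(kept), len(tracks), L_min)
    return kept


def tracks_to_table(tracks: list[Track]) -> pd.DataFrame:
    """Long-format table: track_id, frame, x_um, y_um, intensity."""
    parts = [pd.DataFrame({
        "track_id": t.track_id, "frame": t.frames,
        "x_um": t.x, "y_um": t.y, "intensity": t.intensity,
    }) for t in tracks]
    if not parts:
        return pd.DataFrame(columns=["track_id", "frame", "x_um", "y_um", "intensity"])
    return pd.concat(parts, ignore_index=True)


def tracks_from_table(table: pd.DataFrame) -> list[Track]:
    """Inverse of :func:`tracks_to_table` (lossless round-trip)."""
    out = []
    for tid, g in table.groupby("track_id", sort=True):
        g = g.sort_values("frame")
        out.append(Track(int(tid), g["frame"].to_numpy(), g["x_um"].to_numpy(),
                         g["y_um"].to_numpy(),
                         g["intensity"].to_numpy() if "intensity" in g else None))
    return out
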