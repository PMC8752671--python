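"""Plumbing tracker and TrackMate-style CSV interoperability.

The tracker is a deliberately simple greedy mutual-nearest-neighbor linker
over per-frame connected-component centroids; it is adequate at the plating
densities the simulator produces and is *not* an attempt to reproduce any
particular LAP tracker.
"""

from __future__ import annotations

from pathlib import Path
from typing import List

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import TrackSchemaError
from .simulator import ImageStack, Track

__all__ = [
    "detect_centroids",
    "track_cells",
    "filter_min_length",
    "read_tracks_csv",
    "write_tracks_csv",
]

DETECTION_THRESHOLD = 100  # 8-bit intensity cut for channel-1 detections

REQUIRED_COLUMNS = ("TRACK_ID", "FRAME", "POSITION_X", "POSITION_Y")


def detect_centroids(frame_ch1: np.ndarray, threshold: int = DETECTION_THRESHOLD):
    """Intensity-weighted centroids of connected components above threshold.

    Returns an (n, 2) array of (x, y) positions, ordered by component label.
    """
    mask = frame_ch1 > threshold
    labels, n = ndimage.label(mask)
    if n == 0:
        return np.zeros((0, 2))
    cyx = ndimage.center_of_mass(
        frame_ch1.astype(float), labels, index=range(1, n + 1)
    )
    return np.array([(x, y) for (y, x) in cyx])


def track_cells(
    stack: ImageStack,
    max_link_dist: float | None = None,
    threshold: int = DETECTION_THRESHOLD,
) -> List[Track]:
    """Greedy mutual-nearest-neighbor tracking of channel-1 blobs.

    Frame-to-frame links are accepted shortest-distance-first (each accepted
    pair is a mutual nearest neighbor among the remaining candidates) and
    only within ``max_link_dist``.  Unlinked detections open new tracks and
    gaps are not closed: a missed detection ends the track.
    """
    if stack.n_frames < 2:
        raise ValueError("tracking needs at least 2 frames")
    if max_link_dist is None:
        # 3x the expected per-frame displacement at the default free speed
        # (3 um/min * 2 min / 1 um/px = 6 px per frame)
        max_link_dist = 18.0

    next_id = 0
    open_tracks: dict[int, list] = {}  # cell_id -> list of (frame, x, y)
    open_pos: dict[int, np.ndarray] = {}
    finished: list = []

    for f in range(stack.n_frames):
        dets = detect_centroids(stack.data[f, :, :, 1], threshold)
        ids = sorted(open_pos)
        assigned_tracks: set[int] = set()
        assigned_dets: set[int] = set()
        if ids and len(dets):
            prev = np.array([open_pos[i] for i in ids])
            dist = np.linalg.norm(prev[:, None, :] - dets[None, :, :], axis=2)
            # globally smallest distance first; ties broken by smaller ids
            order = sorted(
                ((dist[a, b], ids[a], b) for a in range(len(ids)) for b in range(len(dets))),
                key=lambda t: (t[0], t[1], t[2]),
            )
            for d, tid, det in order:
                if d > max_link_dist:
                    break
                if tid in assigned_tracks or det in assigned_dets:
                    continue
                assigned_tracks.add(tid)
                assigned_dets.add(det)
                open_tracks[tid].append((f, float(dets[det, 0]), float(dets[det, 1])))
                open_pos[tid] = dets[det]
        for tid in ids:
            if tid not in assigned_tracks:
                finished.append(open_tracks.pop(tid))
                del open_pos[tid]
        for det in range(len(dets)):
            if det not in assigned_dets:
                open_tracks[next_id] = [(f, float(dets[det, 0]), float(dets[det, 1]))]
                open_pos[next_id] = dets[det]
                next_id += 1

    finished.extend(open_tracks[tid] for tid in sorted(open_tracks))
    finished.sort(key=lambda pts: (pts[0][0], pts[0][1], pts[0][2]))
    return [Track(cell_id=k, points=pts) for k, pts in enumerate(finished)]


def filter_min_length(tracks: List[Track], min_frames: int = 20) -> List[Track]:
    """Keep only tracks with at least ``min_frames`` points (order preserved)."""
    if min_frames < 1:
        raise ValueError("min_frames must be >= 1")
    return [t for t in tracks if len(t) >= min_frames]


def read_tracks_csv(path: str | Path) -> List[Track]:
    """Read a TrackMate-compatible CSV export.

    Requires TRACK_ID, FRAME, POSITION_X, POSITION_Y; all other columns are
    ignored.  Non-numeric rows (TrackMate writes up to three extra header
    rows below the column names) are dropped.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TrackSchemaError(
            f"{path}: missing required column(s) {', '.join(missing)}"
        )
    df = df[list(REQUIRED_COLUMNS)].apply(pd.to_numeric, errors="coerce")
    df = df.dropna()
    tracks = []
    for tid, grp in df.groupby("TRACK_ID", sort=True):
        grp = grp.sort_values("FRAME")
        tracks.append(
            Track(
                cell_id=int(tid),
                points=[
                    (int(f), float(x), float(y))
                    for f, x, y in zip(
                        grp["FRAME"], grp["POSITION_X"], grp["POSITION_Y"]
                    )
                ],
            )
        )
    return tracks


def write_tracks_csv(tracks: List[Track], path: str | Path) -> None:
    """Write tracks in the TrackMate-compatible column layout."""
    rows = [
        (t.cell_id, f, x, y) for t in tracks for (f, x, y) in t.points
    ]
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS)).to_csv(path, index=False)
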