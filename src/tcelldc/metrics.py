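"""Classical per-cell discrimination metrics from binary videos and tracks.

Five metrics: overlapped pixels, red (DC) pixels, speed, circularity and
interaction percentage, each averaged over the frames of the per-cell
video.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .simulator import Track
from .videoproc import CellVideo

log = logging.getLogger(__name__)

__all__ = [
    "MetricSummary",
    "overlap_pixels",
    "red_pixels",
    "mean_speed",
    "circularity",
    "interaction_pct",
    "interaction_episodes",
    "summarize",
    "summaries_to_frame",
]


@dataclass
class MetricSummary:
    """Per-cell metric averages over the video's frames."""

    cell_id: int
    mean_red_px: float
    mean_overlap_px: float
    mean_speed: float          # um/min
    mean_circularity: float
    interaction_pct: float     # 0-100
    label: str | None = None


def overlap_pixels(frame: np.ndarray) -> int:
    """Pixels set in both the DC (0) and T-cell (1) channels of a binary frame."""
    return int(np.count_nonzero((frame[..., 0] > 0) & (frame[..., 1] > 0)))


def red_pixels(frame: np.ndarray) -> int:
    """Pixels set in the DC channel of a binary frame."""
    return int(np.count_nonzero(frame[..., 0] > 0))


def mean_speed(
    track_frames: Sequence[int],
    track_xy: np.ndarray,
    frame_interval: float,
    pixel_size: float,
) -> float:
    """Mean link speed (um/min) over consecutive points of a (sub)track.

    Frame numbers need not be consecutive (sampled tracks): each link's
    displacement is divided by its own elapsed time.
    """
    frames = np.asarray(track_frames, dtype=float)
    xy = np.asarray(track_xy, dtype=float)
    if len(frames) < 2:
        raise ValueError("speed needs at least 2 track points")
    disp = np.linalg.norm(np.diff(xy, axis=0), axis=1) * pixel_size
    dt = np.diff(frames) * frame_interval
    return float(np.mean(disp / dt))


# clockwise Moore neighborhood: up, up-right, right, down-right, ...
_MOORE_OFFSETS = [
    (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)
]
_DIR_INDEX = {off: k for k, off in enumerate(_MOORE_OFFSETS)}


def _trace_perimeter(mask: np.ndarray) -> float:
    """Chain-code arc length of the outer boundary.

    Moore-neighbor tracing with backtracking: from each boundary pixel the
    neighborhood is scanned clockwise starting just past the background
    pixel we entered from; tracing stops when the initial move repeats.
    Unit steps count 1, diagonal steps sqrt(2); a single pixel counts 1 so
    the circularity cap applies.
    """
    padded = np.pad(mask.astype(bool), 1)
    ys, xs = np.nonzero(padded)
    if len(ys) == 0:
        raise ValueError("empty mask")
    sy = int(ys.min())
    sx = int(xs[ys == sy].min())
    start = (sy, sx)
    if len(ys) == 1:
        return 1.0
    c = start
    b = (sy, sx - 1)  # background neighbor to the left of the start pixel
    perimeter = 0.0
    first_move = None
    diag = np.sqrt(2.0)
    for _ in range(4 * padded.size):
        b_dir = _DIR_INDEX[(b[0] - c[0], b[1] - c[1])]
        prev = b
        nxt = None
        for k in range(1, 9):
            d = (b_dir + k) % 8
            cand = (c[0] + _MOORE_OFFSETS[d][0], c[1] + _MOORE_OFFSETS[d][1])
            if padded[cand]:
                nxt = cand
                break
            prev = cand
        if nxt is None:  # isolated pixel (cannot happen for len > 1 masks)
            return 1.0
        if first_move is None:
            first_move = (c, nxt)
        elif (c, nxt) == first_move:
            break
        dy, dx = nxt[0] - c[0], nxt[1] - c[1]
        perimeter += diag if dy != 0 and dx != 0 else 1.0
        b = prev
        c = nxt
    return perimeter


def circularity(mask: np.ndarray) -> float:
    """Fiji-style circularity 4*pi*A / P^2 of a binary mask, capped at 1.

    The perimeter is the chain-code length of the outer contour with
    diagonal steps weighted sqrt(2).  Multi-component masks use the largest
    component (logged).
    """
    mask = np.asarray(mask) > 0
    if not mask.any():
        raise ValueError("circularity of an empty mask is undefined")
    labels, n = ndimage.label(mask)
    if n > 1:
        log.debug("multi-component mask: using largest of %d components", n)
        sizes = ndimage.sum_labels(mask, labels, index=range(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    area = float(mask.sum())
    perim = _trace_perimeter(mask)
    if perim <= 0:
        return 1.0
    return float(min(1.0, 4.0 * np.pi * area / perim**2))


def interaction_pct(overlap_series: Sequence[int]) -> float:
    """Percentage of frames with any T cell / DC pixel overlap."""
    series = np.asarray(overlap_series)
    if series.size == 0:
        raise ValueError("empty overlap series")
    return float(100.0 * np.count_nonzero(series > 0) / series.size)


def interaction_episodes(overlap_series: Sequence[int]) -> List[tuple]:
    """Maximal runs of consecutive overlapping frames, as (start, end) inclusive."""
    series = np.asarray(overlap_series) > 0
    episodes = []
    start = None
    for i, v in enumerate(series):
        if v and start is None:
            start = i
        elif not v and start is not None:
            episodes.append((start, i - 1))
            start = None
    if start is not None:
        episodes.append((start, len(series) - 1))
    return episodes


def summarize(
    video: CellVideo,
    track: Track,
    frame_interval: float,
    pixel_size: float,
) -> MetricSummary:
    """All five per-cell metrics, averaged over the video's (sampled) frames.

    Speed uses the track restricted to the video's source frames so the
    metric and the video describe the same observation window.  Frames with
    an empty T-cell mask are skipped in the circularity average.
    """
    overlaps = [overlap_pixels(fr) for fr in video.data]
    reds = [red_pixels(fr) for fr in video.data]
    circs = [
        circularity(fr[..., 1]) for fr in video.data if fr[..., 1].any()
    ]
    source = video.provenance.get("source_frames")
    if source is not None:
        frame_to_idx = {int(f): i for i, (f, _, _) in enumerate(track.points)}
        sel = [frame_to_idx[f] for f in source if f in frame_to_idx]
    else:
        sel = list(range(len(track)))
    frames = track.frames[sel]
    xy = track.xy[sel]
    return MetricSummary(
        cell_id=video.cell_id,
        mean_red_px=float(np.mean(reds)),
        mean_overlap_px=float(np.mean(overlaps)),
        mean_speed=mean_speed(frames, xy, frame_interval, pixel_size),
        mean_circularity=float(np.mean(circs)) if circs else 0.0,
        interaction_pct=interaction_pct(overlaps),
        label=video.label,
    )


def summaries_to_frame(summaries: Sequence[MetricSummary]) -> pd.DataFrame:
    """One row per cell, ready for CSV export."""
    return pd.DataFrame(
        [
            {
                "cell_id": s.cell_id,
                "mean_red_px": s.mean_red_px,
                "mean_overlap_px": s.mean_overlap_px,
                "mean_speed": s.mean_speed,
                "mean_circularity": s.mean_circularity,
                "interaction_pct": s.interaction_pct,
                "label": s.label,
            }
            for s in summaries
        ]
    )
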