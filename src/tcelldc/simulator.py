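"""Agent-based simulator of two-channel T cell / dendritic cell co-culture videos.

The generative model is a persistent random walk for both cell types.  A T
cell that comes within ``capture_radius`` of a DC starts a contact whose
duration is drawn from an exponential dwell-time distribution; while in
contact the cell is anchored near the DC, its speed is scaled by
``arrest_speed_factor`` and its rendered shape relaxes toward the
condition's target circularity.  Cognate cells draw long dwells and sit
deep on the DC (large pixel overlap); non-cognate cells draw short dwells,
touch only the DC rim and are kicked away when the dwell expires.  The
anti-CD40 multipliers lengthen/deepen cognate contacts and shorten
non-cognate ones.

Cells are rendered as anti-aliased constant-area ellipses whose aspect
ratio encodes the current circularity, at 8-bit intensity 200, into
channel 0 (DC, "red") and channel 1 (T cell, "green"); channel 2 is kept
as an all-zero slot so stacks have the 3-channel layout the downstream
classifier expects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
import tifffile

from .errors import FieldSizingError, StackParseError
from .params import Condition, SimParams

__all__ = [
    "ImageStack",
    "Track",
    "GroundTruth",
    "simulate_field",
    "write_stack",
    "read_stack",
    "write_ground_truth",
    "read_ground_truth",
]

CELL_INTENSITY = 200.0
FREE_CIRCULARITY = 0.90
CIRC_DRIFT_RATE = 0.35
CONTACT_ATTRACTION = 0.6


@dataclass
class Track:
    """Ordered per-frame centroid positions of one T cell.

    ``points`` is a list of ``(frame, x, y)`` with x = column, y = row in
    0-based pixel coordinates, origin at the top-left corner.
    """

    cell_id: int
    points: List[Tuple[int, float, float]]
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.points:
            raise ValueError("a track needs at least one point")
        frames = [p[0] for p in self.points]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValueError("track frames must be strictly increasing")

    @property
    def frames(self) -> np.ndarray:
        return np.array([p[0] for p in self.points], dtype=int)

    @property
    def xy(self) -> np.ndarray:
        return np.array([(p[1], p[2]) for p in self.points], dtype=float)

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class GroundTruth:
    """Simulator ground truth: tracks, labels and contact intervals.

    ``contact_intervals[cell_id]`` lists ``(start_frame, end_frame, dc_id)``
    with both endpoints inclusive, sorted and disjoint.
    """

    tracks: List[Track]
    labels: Dict[int, str]
    contact_intervals: Dict[int, List[Tuple[int, int, int]]]
    condition: Condition | None = None

    def contact_fraction(self, cell_id: int, n_frames: int) -> float:
        frames = sum(
            hi - lo + 1 for lo, hi, _ in self.contact_intervals.get(cell_id, [])
        )
        return frames / n_frames


@dataclass
class ImageStack:
    """A time-lapse field: ``data`` is (n_frames, H, W, 3) uint8."""

    data: np.ndarray
    frame_interval: float
    pixel_size: float

    def __post_init__(self) -> None:
        if self.data.ndim != 4 or self.data.shape[-1] != 3:
            raise ValueError("stack data must be (frames, H, W, 3)")
        if self.data.dtype != np.uint8:
            raise ValueError("stack data must be uint8")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple:
        return self.data.shape


# ---------------------------------------------------------------------------
# circularity -> ellipse aspect ratio
# ---------------------------------------------------------------------------

_Q_GRID = np.linspace(0.02, 1.0, 400)


def _circ_of_aspect(q: np.ndarray) -> np.ndarray:
    # area-preserving ellipse: a = r/sqrt(q), b = r*sqrt(q); Ramanujan perimeter
    a = 1.0 / np.sqrt(q)
    b = np.sqrt(q)
    p = np.pi * (3.0 * (a + b) - np.sqrt((3.0 * a + b) * (a + 3.0 * b)))
    return 4.0 * np.pi * np.pi / p**2


_CIRC_GRID = _circ_of_aspect(_Q_GRID)


def _aspect_for_circ(circ: float) -> float:
    """Aspect ratio b/a of the constant-area ellipse with given circularity."""
    return float(np.interp(circ, _CIRC_GRID, _Q_GRID))


def _draw_ellipse(channel, cx, cy, radius, circ, theta) -> None:
    """Max-blend an anti-aliased filled ellipse into a 2-D float canvas."""
    q = _aspect_for_circ(circ)
    a = radius / np.sqrt(q)
    b = radius * np.sqrt(q)
    h, w = channel.shape
    half = int(np.ceil(a)) + 2
    r0, r1 = max(0, int(cy) - half), min(h, int(cy) + half + 1)
    c0, c1 = max(0, int(cx) - half), min(w, int(cx) + half + 1)
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dx = xx - cx
    dy = yy - cy
    ct, st = np.cos(theta), np.sin(theta)
    xr = dx * ct + dy * st
    yr = -dx * st + dy * ct
    rho = np.sqrt((xr / a) ** 2 + (yr / b) ** 2)
    dist = (rho - 1.0) * min(a, b)  # approx signed distance to the boundary
    cov = np.clip(0.5 - dist, 0.0, 1.0)
    region = channel[r0:r1, c0:c1]
    np.maximum(region, CELL_INTENSITY * cov, out=region)


# ---------------------------------------------------------------------------
# agents
# ---------------------------------------------------------------------------


class _Walker:
    """Persistent random walker state for one cell."""

    def __init__(self, rng, pos, speed, persistence):
        self.rng = rng
        self.pos = np.asarray(pos, dtype=float)
        self.speed = float(speed)  # um/min
        self.heading = rng.uniform(0.0, 2.0 * np.pi)
        self.turn_sd = (1.0 - persistence) * np.pi

    def step_vector(self, step_px: float) -> np.ndarray:
        self.heading += self.rng.normal(0.0, self.turn_sd)
        return step_px * np.array([np.cos(self.heading), np.sin(self.heading)])


def _reflect(pos: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect a position into [lo, hi] on both axes."""
    out = pos.copy()
    for k in range(2):
        span = hi - lo
        x = (out[k] - lo) % (2.0 * span)
        out[k] = lo + (x if x <= span else 2.0 * span - x)
    return out


def _place_cells(rng, n, field_px, margin, min_sep, occupied, max_tries=20000):
    """Rejection-sample ``n`` positions with pairwise and cross separation."""
    placed = []
    tries = 0
    while len(placed) < n:
        if tries >= max_tries:
            raise FieldSizingError(
                f"could not place {n} cells with separation {min_sep:.1f}px "
                f"in a {field_px}x{field_px} field after {max_tries} attempts"
            )
        tries += 1
        cand = rng.uniform(margin, field_px - margin, size=2)
        pool = placed + occupied
        if all(np.hypot(*(cand - p)) >= min_sep for p in pool):
            placed.append(cand)
    return placed


def simulate_field(
    params: SimParams, condition: Condition
) -> Tuple[ImageStack, GroundTruth]:
    """Simulate one co-culture field under one condition.

    Returns the rendered 8-bit stack and the exact ground truth (tracks,
    labels, contact intervals).  Identical ``(params, condition)`` including
    ``params.seed`` produce bit-identical output.
    """
    p = params
    p.validate()
    dt = p.frame_interval
    px = p.pixel_size

    # per-agent RNG streams keyed by (seed, kind, index): adding cells does
    # not reshuffle existing ones
    t_rngs = [
        np.random.default_rng(np.random.SeedSequence((p.seed, 0, i)))
        for i in range(p.n_tcells)
    ]
    dc_rngs = [
        np.random.default_rng(np.random.SeedSequence((p.seed, 1, j)))
        for j in range(p.n_dcs)
    ]
    field_rng = np.random.default_rng(np.random.SeedSequence((p.seed, 2)))
    noise_rng = np.random.default_rng(np.random.SeedSequence((p.seed, 3)))

    margin = max(p.tcell_radius, p.dc_radius) + 2.0
    dc_pos = _place_cells(
        field_rng, p.n_dcs, p.field_px, margin, 2.0 * p.dc_radius + 2.0, []
    )
    dcs = [
        _Walker(dc_rngs[j], dc_pos[j], p.speed_dc, p.persistence)
        for j in range(p.n_dcs)
    ]

    if p.start_near_dc and p.n_dcs > 0:
        tc_pos = []
        for i in range(p.n_tcells):
            j = int(field_rng.integers(p.n_dcs))
            ang = field_rng.uniform(0, 2 * np.pi)
            # inside the capture zone: every cell engages a DC at t=0
            r = p.capture_radius * field_rng.uniform(0.5, 0.9)
            cand = dc_pos[j] + r * np.array([np.cos(ang), np.sin(ang)])
            tc_pos.append(_reflect(cand, margin, p.field_px - margin))
    else:
        tc_pos = _place_cells(
            field_rng,
            p.n_tcells,
            p.field_px,
            margin,
            p.capture_radius + 2.0,
            dc_pos,
        )
    # truncated-normal per-cell speeds: keeping the per-frame step below
    # half the excluded-volume separation makes greedy NN linking swap-free
    tcells = [
        _Walker(
            t_rngs[i],
            tc_pos[i],
            float(
                np.clip(
                    t_rngs[i].normal(p.speed_free[0], p.speed_free[1]),
                    0.3 * p.speed_free[0],
                    1.3 * p.speed_free[0],
                )
            ),
            p.persistence,
        )
        for i in range(p.n_tcells)
    ]

    cognate = condition.label == "cognate"
    dwell_mean = p.dwell_mean_cognate if cognate else p.dwell_mean_noncognate
    if condition.acd40:
        dwell_mean *= (
            p.acd40_overlap_gain if cognate else p.acd40_noncog_dwell_factor
        )
    # center-to-center distance held while in contact: deep overlap for
    # cognate ("flattened" onto the DC), rim contact for non-cognate
    if cognate:
        d_contact = p.dc_radius + 0.3 * p.tcell_radius
        if condition.acd40:
            d_contact /= p.acd40_overlap_gain
    else:
        d_contact = p.dc_radius + 0.9 * p.tcell_radius

    # after a contact ends the cell must be able to clear the capture zone
    # before it may re-engage, else short-dwell cells enter a recapture loop
    free_step_px = p.speed_free[0] * dt / px
    refractory_frames = max(2, int(np.ceil(1.5 * p.capture_radius / free_step_px)))
    circ_target_contact = (
        p.contact_circ_cognate if cognate else p.contact_circ_noncognate
    )

    n = p.n_tcells
    contact_dc = np.full(n, -1, dtype=int)
    contact_left = np.zeros(n)  # remaining dwell, minutes
    contact_offset = np.zeros((n, 2))
    refract = np.zeros(n, dtype=int)
    circ = np.full(n, FREE_CIRCULARITY)
    open_interval_start = np.full(n, -1, dtype=int)

    positions = np.zeros((p.n_frames, n, 2))
    circ_hist = np.zeros((p.n_frames, n))
    heading_hist = np.zeros((p.n_frames, n))
    intervals: Dict[int, List[Tuple[int, int, int]]] = {i: [] for i in range(n)}

    lo, hi = margin, p.field_px - margin

    for f in range(p.n_frames):
        if f > 0:
            for dc in dcs:
                dc.pos = _reflect(
                    dc.pos + dc.step_vector(dc.speed * dt / px), lo, hi
                )
            for i, tc in enumerate(tcells):
                if contact_dc[i] >= 0:
                    contact_left[i] -= dt
                    if contact_left[i] <= 0:
                        # dwell expired: close the interval, kick away
                        j = contact_dc[i]
                        intervals[i].append((open_interval_start[i], f - 1, j))
                        contact_dc[i] = -1
                        open_interval_start[i] = -1
                        refract[i] = refractory_frames
                        away = tc.pos - dcs[j].pos
                        nrm = np.hypot(*away)
                        tc.heading = (
                            np.arctan2(away[1], away[0])
                            if nrm > 0
                            else tc.rng.uniform(0, 2 * np.pi)
                        )
                if contact_dc[i] >= 0:
                    # anchored: drift toward the contact point on the DC,
                    # residual motility scaled by the arrest factor
                    j = contact_dc[i]
                    anchor = dcs[j].pos + contact_offset[i] * d_contact
                    jitter = tc.step_vector(
                        tc.speed * p.arrest_speed_factor * dt / px
                    )
                    tc.pos = tc.pos + CONTACT_ATTRACTION * (anchor - tc.pos) + jitter
                else:
                    tc.pos = tc.pos + tc.step_vector(tc.speed * dt / px)
                    if refract[i] > 0:
                        refract[i] -= 1
                tc.pos = _reflect(tc.pos, lo, hi)

            # excluded volume: T cells do not interpenetrate (keeps
            # channel-1 components separable for the tracker)
            min_sep = 2.0 * p.tcell_radius + 6.0
            for _ in range(3):
                overlapping = False
                for a in range(n):
                    for b2 in range(a + 1, n):
                        delta = tcells[a].pos - tcells[b2].pos
                        dist = np.hypot(*delta)
                        if dist < min_sep:
                            overlapping = True
                            direction = (
                                delta / dist if dist > 0 else np.array([1.0, 0.0])
                            )
                            push = 0.5 * (min_sep - dist)
                            tcells[a].pos = _reflect(
                                tcells[a].pos + direction * push, lo, hi
                            )
                            tcells[b2].pos = _reflect(
                                tcells[b2].pos - direction * push, lo, hi
                            )
                if not overlapping:
                    break

        # contact initiation checked at every recorded frame
        for i, tc in enumerate(tcells):
            if contact_dc[i] >= 0 or refract[i] > 0 or p.n_dcs == 0:
                continue
            dists = [np.hypot(*(tc.pos - dc.pos)) for dc in dcs]
            j = int(np.argmin(dists))
            if dists[j] <= p.capture_radius:
                contact_dc[i] = j
                open_interval_start[i] = f
                contact_left[i] = tc.rng.exponential(dwell_mean)
                off = tc.pos - dcs[j].pos
                nrm = np.hypot(*off)
                if nrm == 0:
                    ang = tc.rng.uniform(0, 2 * np.pi)
                    off = np.array([np.cos(ang), np.sin(ang)])
                    nrm = 1.0
                contact_offset[i] = off / nrm

        for i in range(n):
            target = (
                circ_target_contact if contact_dc[i] >= 0 else FREE_CIRCULARITY
            )
            circ[i] += CIRC_DRIFT_RATE * (target - circ[i])
            positions[f, i] = tcells[i].pos
            circ_hist[f, i] = circ[i]
            heading_hist[f, i] = tcells[i].heading
        dc_state = [(dc.pos.copy(), dc.heading) for dc in dcs]
        if f == 0:
            dc_positions = np.zeros((p.n_frames, p.n_dcs, 2))
            dc_headings = np.zeros((p.n_frames, p.n_dcs))
        for j, (pos, hd) in enumerate(dc_state):
            dc_positions[f, j] = pos
            dc_headings[f, j] = hd

    for i in range(n):
        if open_interval_start[i] >= 0:
            intervals[i].append((open_interval_start[i], p.n_frames - 1, contact_dc[i]))

    # ---- rendering ----
    data = np.zeros((p.n_frames, p.field_px, p.field_px, 3), dtype=np.uint8)
    for f in range(p.n_frames):
        red = np.zeros((p.field_px, p.field_px), dtype=np.float64)
        green = np.zeros_like(red)
        for j in range(p.n_dcs):
            x, y = dc_positions[f, j]
            _draw_ellipse(red, x, y, p.dc_radius, 1.0, dc_headings[f, j])
        for i in range(n):
            x, y = positions[f, i]
            _draw_ellipse(
                green, x, y, p.tcell_radius, circ_hist[f, i], heading_hist[f, i]
            )
        if p.noise_sd > 0:
            red += noise_rng.normal(0.0, p.noise_sd, red.shape)
            green += noise_rng.normal(0.0, p.noise_sd, green.shape)
        data[f, :, :, 0] = np.clip(np.rint(red), 0, 255).astype(np.uint8)
        data[f, :, :, 1] = np.clip(np.rint(green), 0, 255).astype(np.uint8)

    tracks = [
        Track(
            cell_id=i,
            points=[
                (f, float(positions[f, i, 0]), float(positions[f, i, 1]))
                for f in range(p.n_frames)
            ],
            label=condition.label,
        )
        for i in range(n)
    ]
    gt = GroundTruth(
        tracks=tracks,
        labels={i: condition.label for i in range(n)},
        contact_intervals=intervals,
        condition=condition,
    )
    stack = ImageStack(data=data, frame_interval=dt, pixel_size=px)
    return stack, gt


# ---------------------------------------------------------------------------
# stack / ground-truth I/O
# ---------------------------------------------------------------------------


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as multi-page TIFF, channel-interleaved per frame.

    Page order is frame-major: frame 0 channel 0, frame 0 channel 1,
    frame 0 channel 2, frame 1 channel 0, ...  Metadata (frame interval,
    pixel size, channel semantics) goes into the ImageDescription tag.
    """
    meta = {
        "frame_interval_min": stack.frame_interval,
        "pixel_size_um": stack.pixel_size,
        "channels": ["dc_red", "tcell_green", "empty"],
        "page_order": "frame_major_channel_interleaved",
    }
    pages = stack.data.transpose(0, 3, 1, 2).reshape(
        -1, stack.data.shape[1], stack.data.shape[2]
    )
    tifffile.imwrite(
        str(path),
        pages,
        photometric="minisblack",
        description=json.dumps(meta),
    )


def read_stack(path: str | Path) -> ImageStack:
    """Read a stack written by :func:`write_stack`."""
    try:
        with tifffile.TiffFile(str(path)) as tif:
            desc = tif.pages[0].description
            pages = []
            for k, page in enumerate(tif.pages):
                try:
                    pages.append(page.asarray())
                except Exception as exc:  # corrupt page
                    raise StackParseError(
                        f"failed to decode page {k} of {path}: {exc}"
                    ) from exc
    except StackParseError:
        raise
    except Exception as exc:
        raise StackParseError(f"failed to parse TIFF {path}: {exc}") from exc
    try:
        meta = json.loads(desc)
    except (TypeError, json.JSONDecodeError) as exc:
        raise StackParseError(f"missing/invalid metadata in {path}") from exc
    arr = np.stack(pages)
    if arr.shape[0] % 3 != 0:
        raise StackParseError(
            f"{path}: page count {arr.shape[0]} is not a multiple of 3 channels"
        )
    data = arr.reshape(-1, 3, arr.shape[1], arr.shape[2]).transpose(0, 2, 3, 1)
    return ImageStack(
        data=np.ascontiguousarray(data),
        frame_interval=float(meta["frame_interval_min"]),
        pixel_size=float(meta["pixel_size_um"]),
    )


def write_ground_truth(gt: GroundTruth, tracks_path, labels_path) -> None:
    """Write ground truth as two CSVs: tracks and labels."""
    import pandas as pd

    rows = [
        (t.cell_id, f, x, y) for t in gt.tracks for (f, x, y) in t.points
    ]
    pd.DataFrame(rows, columns=["cell_id", "frame", "x", "y"]).to_csv(
        tracks_path, index=False
    )
    cond = gt.condition
    lab_rows = [
        (
            cid,
            lab,
            (cond.label if cond else ""),
            (int(cond.acd40) if cond else ""),
        )
        for cid, lab in sorted(gt.labels.items())
    ]
    pd.DataFrame(
        lab_rows, columns=["cell_id", "label", "condition", "acd40"]
    ).to_csv(labels_path, index=False)


def read_ground_truth(tracks_path, labels_path) -> GroundTruth:
    """Read the CSV pair written by :func:`write_ground_truth`."""
    import pandas as pd

    tdf = pd.read_csv(tracks_path)
    ldf = pd.read_csv(labels_path)
    labels = dict(zip(ldf["cell_id"].astype(int), ldf["label"]))
    tracks = []
    for cid, grp in tdf.groupby("cell_id", sort=True):
        grp = grp.sort_values("frame")
        tracks.append(
            Track(
                cell_id=int(cid),
                points=[
                    (int(f), float(x), float(y))
                    for f, x, y in zip(grp["frame"], grp["x"], grp["y"])
                ],
                label=labels.get(int(cid)),
            )
        )
    return GroundTruth(tracks=tracks, labels=labels, contact_intervals={})
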