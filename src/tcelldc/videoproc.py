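"""Per-cell video extraction: crop, mask, blur, binarize, frame-sample.

Produces the fixed-size binary videos the classifier consumes.  The two
channels are thresholded differently on purpose: the DC ("red") channel
uses a single Huang fuzzy-entropy threshold computed on the *full field
before cropping*, shared by every cell from that field, while the T-cell
("green") channel uses one Otsu threshold per cell computed *after*
cropping and neighbor masking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import dilation, disk

from .errors import CropSizingError, FrameExclusionError
from .params import PipelineParams
from .simulator import ImageStack, Track

log = logging.getLogger(__name__)

__all__ = [
    "CellVideo",
    "crop_window",
    "huang_threshold",
    "otsu_threshold",
    "field_dc_threshold",
    "mask_neighbors",
    "binarize",
    "sample_frames",
    "process_cell",
    "process_field",
]


@dataclass
class CellVideo:
    """A binary per-cell video: (T, crop, crop, 3) with values in {0, 1}.

    Channel 2 is kept all-zero so the array layout matches the 3-channel
    input shape the classifier was designed around.
    """

    data: np.ndarray
    cell_id: int
    label: str | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.ndim != 4 or self.data.shape[-1] != 3:
            raise ValueError("cell video must be (T, H, W, 3)")
        vals = np.unique(self.data)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("cell video must be strictly binary")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]


def crop_window(
    centroid: Tuple[float, float], field_shape: Tuple[int, int], crop_px: int = 101
) -> Tuple[int, int, int, int]:
    """Half-open (row_lo, row_hi, col_lo, col_hi) of the crop around a centroid.

    The window is centered on the rounded centroid; when that would cross a
    field border it is shifted to lie fully inside, so edge cells sit
    off-center.  Centroid is (x, y); rounding is to nearest with ties toward
    the larger index.
    """
    h, w = field_shape
    if h < crop_px or w < crop_px:
        raise CropSizingError(
            f"field {h}x{w} smaller than crop window {crop_px}"
        )
    x, y = centroid
    half = crop_px // 2
    row = int(np.floor(y + 0.5))
    col = int(np.floor(x + 0.5))
    row_lo = min(max(row - half, 0), h - crop_px)
    col_lo = min(max(col - half, 0), w - crop_px)
    return row_lo, row_lo + crop_px, col_lo, col_lo + crop_px


def huang_threshold(histogram: np.ndarray) -> int:
    """Huang–Wang fuzzy-entropy threshold of a 256-bin histogram.

    Scans every cut level t, assigns each gray level a fuzzy membership
    based on its distance to the mean of its class (levels <= t vs > t),
    and returns the t minimizing total Shannon fuzzy entropy.  Foreground
    is ``pixel > t``.
    """
    hist = np.asarray(histogram, dtype=np.float64)
    if hist.ndim != 1 or hist.size != 256:
        raise ValueError("expected a 256-bin histogram")
    if hist.sum() <= 0:
        raise ValueError("histogram is empty")
    nz = np.nonzero(hist)[0]
    first, last = nz[0], nz[-1]
    if first == last:
        return int(first)

    levels = np.arange(256, dtype=np.float64)
    w = hist * levels
    cum_n = np.cumsum(hist)
    cum_w = np.cumsum(w)
    total_n, total_w = cum_n[-1], cum_w[-1]
    c = float(last - first)

    cuts, entropies = [], []
    for t in range(first, last):
        n0 = cum_n[t]
        n1 = total_n - n0
        if n0 == 0 or n1 == 0:
            continue
        mu0 = cum_w[t] / n0
        mu1 = (total_w - cum_w[t]) / n1
        u = np.empty(256)
        u[: t + 1] = 1.0 / (1.0 + np.abs(levels[: t + 1] - mu0) / c)
        u[t + 1 :] = 1.0 / (1.0 + np.abs(levels[t + 1 :] - mu1) / c)
        with np.errstate(divide="ignore", invalid="ignore"):
            s_terms = -u * np.log(u) - (1.0 - u) * np.log(1.0 - u)
        s_terms[~np.isfinite(s_terms)] = 0.0  # u == 1 contributes zero entropy
        cuts.append(t)
        entropies.append(float(np.dot(hist, s_terms)))
    # ties (flat-entropy plateaus, e.g. well-separated two-delta histograms)
    # resolve to the middle of the plateau
    entropies = np.asarray(entropies)
    plateau = np.nonzero(entropies <= entropies.min() + 1e-12)[0]
    return int(cuts[plateau[len(plateau) // 2]])


def otsu_threshold(histogram: np.ndarray) -> int:
    """Otsu threshold of a 256-bin histogram (foreground is ``pixel > t``)."""
    hist = np.asarray(histogram, dtype=np.float64)
    if hist.sum() <= 0:
        raise ValueError("histogram is empty")
    nz = np.nonzero(hist)[0]
    if nz[0] == nz[-1]:
        return int(nz[0])
    t = threshold_otsu(hist=(hist, np.arange(256)))
    return int(t)


def _stack_histogram(frames: np.ndarray) -> np.ndarray:
    return np.bincount(
        np.clip(np.rint(frames), 0, 255).astype(np.uint8).ravel(), minlength=256
    )


def field_dc_threshold(stack: ImageStack, blur_sigma: float = 1.0) -> float:
    """Huang threshold of the blurred full-field DC channel, one per field.

    Computed over the pooled histogram of every frame prior to cropping;
    shared by all cells extracted from the field.  Returns +inf (all-zero
    binarization) for a constant channel.
    """
    blurred = np.stack(
        [
            ndimage.gaussian_filter(stack.data[f, :, :, 0].astype(np.float32), blur_sigma)
            for f in range(stack.n_frames)
        ]
    )
    if blurred.max() == blurred.min():
        log.warning("DC channel is constant; threshold set to +inf")
        return np.inf
    return float(huang_threshold(_stack_histogram(blurred)))


def mask_neighbors(
    cropped: np.ndarray, rois: Sequence[np.ndarray]
) -> np.ndarray:
    """Zero channel-1 pixels outside the per-frame ROI; channel 0 untouched.

    ``rois`` holds one boolean mask per frame covering the tracked cell.
    An empty ROI blanks that frame's channel 1 (warning, not an error).
    """
    out = cropped.copy()
    for f, roi in enumerate(rois):
        if not roi.any():
            log.warning("empty ROI in frame %d; channel 1 blanked", f)
            out[f, :, :, 1] = 0
        else:
            out[f, :, :, 1] = np.where(roi, out[f, :, :, 1], 0)
    return out


def _roi_for_frame(
    ch1: np.ndarray, blur_sigma: float, dilate_px: int = 2
) -> np.ndarray:
    """ROI of the tracked cell: provisional Otsu component nearest the center,
    dilated.  The crop is centered on the track centroid, so the component
    closest to the window center is the tracked cell."""
    blurred = ndimage.gaussian_filter(ch1.astype(np.float32), blur_sigma)
    if blurred.max() == blurred.min():
        return np.zeros(ch1.shape, dtype=bool)
    t = otsu_threshold(_stack_histogram(blurred))
    mask = blurred > t
    labels, n = ndimage.label(mask)
    if n == 0:
        return np.zeros(ch1.shape, dtype=bool)
    cy, cx = (np.array(ch1.shape) - 1) / 2.0
    yy, xx = np.nonzero(mask)
    d2 = (yy - cy) ** 2 + (xx - cx) ** 2
    target_label = labels[yy[np.argmin(d2)], xx[np.argmin(d2)]]
    roi = labels == target_label
    return dilation(roi, disk(dilate_px)).astype(bool)


def binarize(
    cropped: np.ndarray, dc_threshold: float, blur_sigma: float = 1.0
) -> np.ndarray:
    """Blur and binarize a cropped (T, H, W, 3) per-cell video.

    Channel 0 uses the field-level ``dc_threshold``; channel 1 uses one Otsu
    threshold computed from the pooled histogram of the blurred cropped
    frames.  Output values are {0, 1} uint8; channel 2 stays zero.
    """
    t_frames, h, w, _ = cropped.shape
    blurred = np.zeros((t_frames, h, w, 2), dtype=np.float32)
    for f in range(t_frames):
        for ch in range(2):
            blurred[f, :, :, ch] = ndimage.gaussian_filter(
                cropped[f, :, :, ch].astype(np.float32), blur_sigma
            )
    out = np.zeros_like(cropped, dtype=np.uint8)
    out[..., 0] = (blurred[..., 0] > dc_threshold).astype(np.uint8)
    green = blurred[..., 1]
    if green.max() == green.min():
        log.warning("constant T-cell channel; binarized to all-zero")
    else:
        t_green = otsu_threshold(_stack_histogram(green))
        out[..., 1] = (green > t_green).astype(np.uint8)
    return out


def sample_frames(n_available: int, mode: str = "uniform", k: int = 20) -> List[int]:
    """Source frame indices for the fixed-length video.

    Uniform mode returns exactly 20 indices anchored at frame 0: the first
    20 frames when 20-39 are available, every other frame when 40-59, and
    every third frame from 60 on (first 20 of the strided sequence).
    ``consecutive_k`` mode returns the first k frames.
    """
    if mode == "uniform":
        if n_available < 20:
            raise FrameExclusionError(
                f"only {n_available} frames available; cells with fewer than "
                "20 frames are excluded"
            )
        if n_available < 40:
            stride = 1
        elif n_available < 60:
            stride = 2
        else:
            stride = 3
        return list(range(0, 20 * stride, stride))
    if mode == "consecutive_k":
        if n_available < k:
            raise FrameExclusionError(
                f"only {n_available} frames available; need {k} consecutive"
            )
        return list(range(k))
    raise ValueError(f"unknown sampling mode {mode!r}")


def process_cell(
    stack: ImageStack,
    track: Track,
    params: PipelineParams | None = None,
    dc_threshold: float | None = None,
) -> CellVideo:
    """Run the full per-cell pipeline: crop -> mask -> blur+binarize -> sample."""
    params = params or PipelineParams()
    if dc_threshold is None:
        dc_threshold = field_dc_threshold(stack, params.blur_sigma)

    idx = sample_frames(
        len(track),
        params.sampling_mode,
        params.consecutive_k,
    )
    frames = track.frames
    xy = track.xy
    crop = params.crop_px
    h, w = stack.data.shape[1:3]
    cropped = np.zeros((len(idx), crop, crop, 3), dtype=stack.data.dtype)
    rois = []
    for out_f, i in enumerate(idx):
        f = int(frames[i])
        r0, r1, c0, c1 = crop_window((xy[i, 0], xy[i, 1]), (h, w), crop)
        window = stack.data[f, r0:r1, c0:c1, :]
        cropped[out_f] = window
        rois.append(_roi_for_frame(window[:, :, 1], params.blur_sigma))
    masked = mask_neighbors(cropped, rois)
    binary = binarize(masked, dc_threshold, params.blur_sigma)
    return CellVideo(
        data=binary,
        cell_id=track.cell_id,
        label=track.label,
        provenance={
            "sampling_mode": params.sampling_mode,
            "source_frames": [int(frames[i]) for i in idx],
            "dc_threshold": float(dc_threshold),
        },
    )


def process_field(
    stack: ImageStack,
    tracks: Sequence[Track],
    params: PipelineParams | None = None,
) -> List[CellVideo]:
    """Process every sufficiently long track of a field into a CellVideo."""
    params = params or PipelineParams()
    dc_t = field_dc_threshold(stack, params.blur_sigma)
    out = []
    for track in tracks:
        min_needed = (
            20 if params.sampling_mode == "uniform" else params.consecutive_k
        )
        if len(track) < max(min_needed, params.min_track_frames):
            continue
        out.append(process_cell(stack, track, params, dc_t))
    return out
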