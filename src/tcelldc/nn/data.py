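"""Dataset assembly for the classifier: label encoding, stratified
splitting, shift augmentation and array conversion."""

from __future__ import annotations

from typing import List, Sequence, Tuple

import numpy as np
from skimage.measure import block_reduce

from ..errors import StratificationError
from ..params import TrainConfig
from ..videoproc import CellVideo

__all__ = [
    "LABEL_TO_CLASS",
    "videos_to_arrays",
    "split_dataset",
    "augment",
    "downsample_video",
]

LABEL_TO_CLASS = {"non-cognate": 0, "cognate": 1}


def downsample_video(data: np.ndarray, factor: int) -> np.ndarray:
    """Spatial max-pool downsampling of a (T, H, W, C) binary video.

    Max pooling keeps the data binary and preserves thin overlap regions.
    Edges are zero-padded up to a multiple of ``factor``.
    """
    if factor == 1:
        return data
    return block_reduce(data, (1, factor, factor, 1), np.max)


def videos_to_arrays(
    videos: Sequence[CellVideo], spatial_factor: int = 1
) -> Tuple[np.ndarray, np.ndarray]:
    """Stack cell videos into (N, T, h, w, 3) float32 X and int class vector y."""
    xs = [
        downsample_video(v.data, spatial_factor).astype(np.float32) for v in videos
    ]
    y = np.array([LABEL_TO_CLASS[v.label] for v in videos], dtype=np.int64)
    return np.stack(xs), y


def _allocate(counts_per_class: List[int], fracs: Tuple[float, ...]):
    """Largest-remainder allocation per class, ties resolved toward the
    split with the largest remaining global deficit (keeps e.g. a 5+5 set
    at a global 8/1/1)."""
    n_total = sum(counts_per_class)
    global_target = [n_total * f for f in fracs]
    assigned = [0.0] * len(fracs)
    plans = []
    for n in counts_per_class:
        base = [int(np.floor(n * f)) for f in fracs]
        remainders = [n * f - b for f, b in zip(fracs, base)]
        short = n - sum(base)
        order = sorted(
            range(len(fracs)),
            key=lambda s: (
                -remainders[s],
                -(global_target[s] - assigned[s] - base[s]),
                s,
            ),
        )
        for s in order[:short]:
            base[s] += 1
        for s, b in enumerate(base):
            assigned[s] += b
        plans.append(base)
    return plans


def split_dataset(
    videos: Sequence, cfg: TrainConfig | None = None
) -> Tuple[list, list, list]:
    """Deterministic stratified train/val/test partition of labeled videos.

    The partition is disjoint and exhaustive, stratified by ``label`` and
    driven entirely by ``cfg.seed``.
    """
    cfg = cfg or TrainConfig()
    labels = [v.label for v in videos]
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise StratificationError(
            f"both labels must be present, got only {classes}"
        )
    rng = np.random.default_rng(cfg.seed)
    per_class_idx = [
        [i for i, lab in enumerate(labels) if lab == c] for c in classes
    ]
    plans = _allocate([len(ix) for ix in per_class_idx], cfg.split)
    parts: Tuple[list, list, list] = ([], [], [])
    for idx, plan in zip(per_class_idx, plans):
        idx = list(rng.permutation(idx))
        lo = 0
        for s, count in enumerate(plan):
            parts[s].extend(idx[lo : lo + count])
            lo += count
    return tuple([videos[i] for i in sorted(part)] for part in parts)


def augment(video: CellVideo, max_shift: int, rng: np.random.Generator) -> CellVideo:
    """Shift a whole binary video by one random (dx, dy); zero fill.

    The same shift is applied to every frame so motion cues are preserved.
    """
    dx, dy = (int(v) for v in rng.integers(-max_shift, max_shift + 1, 2))
    data = video.data
    out = np.zeros_like(data)
    h, w = data.shape[1], data.shape[2]
    src_r = slice(max(0, -dy), min(h, h - dy))
    dst_r = slice(max(0, dy), min(h, h + dy))
    src_c = slice(max(0, -dx), min(w, w - dx))
    dst_c = slice(max(0, dx), min(w, w + dx))
    out[:, dst_r, dst_c, :] = data[:, src_r, src_c, :]
    prov = dict(video.provenance)
    prov["augment_shift"] = (dx, dy)
    return CellVideo(
        data=out, cell_id=video.cell_id, label=video.label, provenance=prov
    )
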