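"""ROC/AUC evaluation, metric-vs-model comparison, cross-population
generalization and the frame-count ablation experiment."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .errors import AlignmentError
from .metrics import MetricSummary
from .nn.data import LABEL_TO_CLASS, split_dataset, videos_to_arrays
from .nn.model import CNNLSTM, ModelSpec, build_model, train_model
from .params import TrainConfig
from .videoproc import CellVideo

__all__ = [
    "ROCCurve",
    "AblationResult",
    "roc_auc",
    "compare_methods",
    "run_ablation",
    "cross_population_eval",
    "METRIC_ORIENTATION",
]

# Orientation fixed a priori from the biology: contact-driven metrics are
# higher in cognate cells, motility/shape metrics lower.
METRIC_ORIENTATION = {
    "mean_overlap_px": "higher_is_cognate",
    "mean_red_px": "higher_is_cognate",
    "interaction_pct": "higher_is_cognate",
    "mean_speed": "lower_is_cognate",
    "mean_circularity": "lower_is_cognate",
}


@dataclass
class ROCCurve:
    """ROC sweep with trapezoidal AUC; positive class is cognate."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    orientation: str = "higher_is_cognate"


@dataclass
class AblationResult:
    """Seed-averaged AUC per consecutive-frame count."""

    frame_counts: List[int]
    auc_mean: Dict[int, float]
    auc_per_seed: Dict[int, List[float]] = field(default_factory=dict)


def _to_binary_labels(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "UO":
        arr = np.array([LABEL_TO_CLASS[str(v)] for v in arr])
    return arr.astype(int)


def roc_auc(
    scores: Sequence[float],
    labels: Sequence,
    orientation: str = "higher_is_cognate",
) -> ROCCurve:
    """ROC curve and AUC of a score against cognate/non-cognate labels.

    ``lower_is_cognate`` negates the scores first (used for speed and
    circularity).  AUC equals the probability that a random cognate cell
    outscores a random non-cognate one, ties counting one half.
    """
    y = _to_binary_labels(labels)
    s = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    if len(set(y)) < 2:
        raise ValueError("both classes must be present")
    if orientation == "lower_is_cognate":
        s = -s
    elif orientation != "higher_is_cognate":
        raise ValueError(f"unknown orientation {orientation!r}")
    fpr, tpr, thr = _sk_roc_curve(y, s, drop_intermediate=False)
    return ROCCurve(
        thresholds=thr,
        fpr=fpr,
        tpr=tpr,
        auc=float(_trapezoid_auc(fpr, tpr)),
        orientation=orientation,
    )


def compare_methods(
    model: CNNLSTM,
    test_videos: Sequence[CellVideo],
    test_summaries: Sequence[MetricSummary],
    spatial_factor: int = 1,
) -> Dict[str, float]:
    """AUC of the deep model and of each classical metric on the same cells.

    ``test_summaries`` must describe exactly the cells of ``test_videos``
    (same ids, same order); anything else is an alignment error.
    """
    vid_ids = [v.cell_id for v in test_videos]
    sum_ids = [s.cell_id for s in test_summaries]
    if vid_ids != sum_ids:
        raise AlignmentError(
            f"videos and summaries describe different cells: "
            f"{vid_ids[:5]}... vs {sum_ids[:5]}..."
        )
    x, y = videos_to_arrays(test_videos, spatial_factor)
    table = {"deep_model": roc_auc(model.predict_proba(x), y).auc}
    for metric, orientation in METRIC_ORIENTATION.items():
        values = [getattr(s, metric) for s in test_summaries]
        table[metric] = roc_auc(values, y, orientation).auc
    return table


def _truncate_videos(videos: Sequence[CellVideo], k: int) -> List[CellVideo]:
    out = []
    for v in videos:
        prov = dict(v.provenance)
        prov["sampling_mode"] = "consecutive_k"
        prov["source_frames"] = prov.get("source_frames", list(range(v.n_frames)))[:k]
        out.append(
            CellVideo(data=v.data[:k], cell_id=v.cell_id, label=v.label,
                      provenance=prov)
        )
    return out


def _train_eval_auc(
    videos: Sequence[CellVideo],
    spec: ModelSpec,
    cfg: TrainConfig,
    spatial_factor: int,
) -> Tuple[float, CNNLSTM, list, list]:
    """Split, train a fresh model and return held-out AUC."""
    tr, va, te = split_dataset(videos, cfg)
    x_tr, y_tr = videos_to_arrays(tr, spatial_factor)
    x_va, y_va = videos_to_arrays(va, spatial_factor)
    x_te, y_te = videos_to_arrays(te, spatial_factor)
    model = build_model(dataclasses.replace(spec, input_shape=x_tr.shape[1:]))
    model, history = train_model(model, (x_tr, y_tr), (x_va, y_va), cfg)
    curve = roc_auc(model.predict_proba(x_te), y_te)
    return curve.auc, model, te, history


def run_ablation(
    videos: Sequence[CellVideo],
    spec: ModelSpec,
    cfg: TrainConfig,
    counts: Sequence[int] = (20, 10, 5, 2),
    seeds: Sequence[int] = (0, 1, 2, 3, 4),
    spatial_factor: int = 1,
) -> AblationResult:
    """Fig-4c-style ablation: truncate to the first k consecutive frames,
    train a fresh model per (count, seed), report seed-averaged test AUC.

    Source videos must have at least ``max(counts)`` frames.
    """
    n_frames = min(v.n_frames for v in videos)
    if n_frames < max(counts):
        raise ValueError(
            f"source videos have {n_frames} frames; need >= {max(counts)}"
        )
    per_seed: Dict[int, List[float]] = {k: [] for k in counts}
    for k in counts:
        trunc = _truncate_videos(videos, k)
        for seed in seeds:
            run_cfg = dataclasses.replace(cfg, seed=seed)
            auc_val, _, _, _ = _train_eval_auc(
                trunc, spec, run_cfg, spatial_factor
            )
            per_seed[k].append(auc_val)
    return AblationResult(
        frame_counts=list(counts),
        auc_mean={k: float(np.mean(v)) for k, v in per_seed.items()},
        auc_per_seed=per_seed,
    )


def cross_population_eval(
    model: CNNLSTM,
    other_videos: Sequence[CellVideo],
    spatial_factor: int = 1,
) -> ROCCurve:
    """AUC of an unmodified trained model on a different population."""
    x, y = videos_to_arrays(other_videos, spatial_factor)
    return roc_auc(model.predict_proba(x), y)
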