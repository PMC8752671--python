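"""Synthetic population builders: fields -> labeled per-cell videos.

Convenience glue used by the evaluation layer, the CLI and the test
benchmarks.  A "population" is a pile of labeled CellVideos plus their
ground-truth tracks, assembled from as many simulated fields as needed.
"""

from __future__ import annotations

import dataclasses
from typing import List, Sequence, Tuple

from .metrics import MetricSummary, summarize
from .params import Condition, PipelineParams, SimParams
from .simulator import Track, simulate_field
from .videoproc import CellVideo, process_field

__all__ = [
    "make_population",
    "summarize_population",
    "q4_like",
    "strain_b",
    "BENCHMARK_SIM",
]

# Scaled-down but strongly separable co-culture used by the classifier
# benchmarks: small field, few cells, T cells seeded near DCs so class
# structure emerges within the 45-frame window.
BENCHMARK_SIM = SimParams(
    field_px=224,
    n_frames=45,
    n_tcells=6,
    n_dcs=2,
    start_near_dc=True,
    noise_sd=1.0,
    dwell_mean_cognate=150.0,
    dwell_mean_noncognate=1.0,
    arrest_speed_factor=0.1,
    contact_circ_cognate=0.40,
    contact_circ_noncognate=0.90,
)


def q4_like(params: SimParams) -> SimParams:
    """Lower-affinity population: arrested cells stay partly motile
    (intermediate arrest factor), contact structure otherwise unchanged."""
    return dataclasses.replace(params, arrest_speed_factor=0.5)


def strain_b(params: SimParams) -> SimParams:
    """A different-strain population: 20% faster cells, 20% shorter dwells."""
    return dataclasses.replace(
        params,
        speed_free=(params.speed_free[0] * 1.2, params.speed_free[1]),
        dwell_mean_cognate=params.dwell_mean_cognate * 0.8,
        dwell_mean_noncognate=params.dwell_mean_noncognate * 0.8,
    )


def make_population(
    n_per_class: int,
    params: SimParams | None = None,
    acd40: bool = True,
    seed: int = 0,
    pipeline: PipelineParams | None = None,
) -> Tuple[List[CellVideo], List[Track]]:
    """Simulate fields until ``n_per_class`` processed cells exist per label.

    Each field is a single-condition well.  Per-cell videos come from the
    ground-truth tracks (the plumbing tracker is exercised separately), so
    every simulated T cell yields one video.  Field seeds are derived as
    ``seed*10000 + field_index`` for reproducibility.
    """
    params = params or BENCHMARK_SIM
    pipeline = pipeline or PipelineParams()
    videos: List[CellVideo] = []
    tracks: List[Track] = []
    field_idx = 0
    for label in ("cognate", "non-cognate"):
        count = 0
        while count < n_per_class:
            p = dataclasses.replace(params, seed=seed * 10000 + field_idx)
            field_idx += 1
            stack, gt = simulate_field(p, Condition(label=label, acd40=acd40))
            cell_videos = process_field(stack, gt.tracks, pipeline)
            by_id = {t.cell_id: t for t in gt.tracks}
            for video in cell_videos:
                if count >= n_per_class:
                    break
                track = by_id[video.cell_id]
                new_id = len(videos)
                video.cell_id = new_id
                videos.append(video)
                tracks.append(dataclasses.replace(track, cell_id=new_id))
                count += 1
    return videos, tracks


def summarize_population(
    videos: Sequence[CellVideo],
    tracks: Sequence[Track],
    frame_interval: float,
    pixel_size: float,
) -> List[MetricSummary]:
    """Metric summaries for an aligned (videos, tracks) population."""
    return [
        summarize(v, t, frame_interval, pixel_size)
        for v, t in zip(videos, tracks)
    ]
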