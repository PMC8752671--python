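"""Shared fixtures.

The expensive artifacts (simulated populations, one trained classifier)
are session-scoped and shared between the unit suite and the acceptance
suite to keep the default run inside its time budget.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from tcelldc import datasets
from tcelldc.nn import ModelSpec, build_model, split_dataset, train_model, videos_to_arrays
from tcelldc.params import Condition, PipelineParams, SimParams, TrainConfig
from tcelldc.simulator import simulate_field

# reduced-scale training configuration used by every classifier benchmark;
# the published protocol (20 epochs, lr 1e-4, l2 1e-2) is impractically
# slow to converge on a few hundred CPU-trained videos
BENCH_SPATIAL_FACTOR = 6
BENCH_TRAIN = TrainConfig(epochs=12, seed=0, batch_size=16, shift_augment_max=2)
BENCH_SPEC = dict(learning_rate=1e-3, lstm_l2=1e-3, init_seed=0)


@pytest.fixture(scope="session")
def small_field():
    """One default-parameter cognate field plus ground truth (fast)."""
    params = SimParams(seed=11)
    stack, gt = simulate_field(params, Condition("cognate", True))
    return params, stack, gt


@pytest.fixture(scope="session")
def noncog_field():
    params = SimParams(seed=12)
    stack, gt = simulate_field(params, Condition("non-cognate", True))
    return params, stack, gt


@pytest.fixture(scope="session")
def benchmark_population():
    """80 cells/class, +aCD40, uniform-sampled 20-frame videos."""
    videos, tracks = datasets.make_population(80, seed=7)
    return videos, tracks


@pytest.fixture(scope="session")
def trained_benchmark(benchmark_population):
    """One trained scaled-down classifier plus its held-out test split."""
    videos, _ = benchmark_population
    tr, va, te = split_dataset(videos, BENCH_TRAIN)
    x_tr, y_tr = videos_to_arrays(tr, BENCH_SPATIAL_FACTOR)
    x_va, y_va = videos_to_arrays(va, BENCH_SPATIAL_FACTOR)
    spec = ModelSpec(input_shape=x_tr.shape[1:], **BENCH_SPEC)
    model = build_model(spec)
    model, history = train_model(model, (x_tr, y_tr), (x_va, y_va), BENCH_TRAIN)
    return {
        "model": model,
        "history": history,
        "test_videos": te,
        "spatial_factor": BENCH_SPATIAL_FACTOR,
        "spec": spec,
    }


@pytest.fixture(scope="session")
def metric_population():
    """200 cells/class at default density, +aCD40 (metric-direction suite)."""
    params = SimParams()  # defaults; seed overridden per field
    videos, tracks = datasets.make_population(200, params=params, acd40=True, seed=21)
    summaries = datasets.summarize_population(
        videos, tracks, params.frame_interval, params.pixel_size
    )
    return summaries
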