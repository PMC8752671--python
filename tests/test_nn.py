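import dataclasses

import numpy as np
import pytest

from tcelldc.errors import (
    InputShapeError,
    LayerNotFoundError,
    StratificationError,
)
from tcelldc.nn import (
    ModelSpec,
    augment,
    build_model,
    downsample_video,
    grad_cam,
    load_model,
    save_model,
    split_dataset,
    train_model,
    videos_to_arrays,
)
from tcelldc.nn.layers import LSTM, BatchNorm, Conv2D, Dense, MaxPool2D
from tcelldc.nn.model import _softmax
from tcelldc.params import TrainConfig
from tcelldc.videoproc import CellVideo

TINY_SPEC = ModelSpec(
    input_shape=(3, 10, 10, 3),
    conv_blocks=((4, 2), (4,), (6,), (4,)),
    lstm_units=8,
    dense_units=6,
    init_seed=3,
)


def _toy_videos(n, rng, frames=4, size=15):
    videos = []
    for i in range(n):
        label = "cognate" if i % 2 == 0 else "non-cognate"
        data = np.zeros((frames, size, size, 3), dtype=np.uint8)
        data[:, 4:9, 4:9, 1] = 1
        if label == "cognate":
            data[:, 4:9, 4:9, 0] = 1  # overlapping DC
        else:
            data[:, 10:14, 10:14, 0] = 1
        videos.append(CellVideo(data=data, cell_id=i, label=label))
    return videos


# ---------------------------------------------------------------------------
# layer-level gradient checks against central finite differences
# ---------------------------------------------------------------------------


def _fd_check(layer, x, train=True, eps=1e-2, tol=5e-3, floor=1e-2):
    rng = np.random.default_rng(0)
    out = layer.forward(x, train)
    r = np.random.default_rng(1).random(out.shape).astype(np.float32)
    gin = layer.backward(r)

    def loss():
        out = layer.forward(x, train).astype(np.float64)
        return float((out * r.astype(np.float64)).sum())

    for k, p in layer.params.items():
        for i in rng.choice(p.size, size=min(4, p.size), replace=False):
            orig = p.flat[i]
            p.flat[i] = orig + eps
            lp = loss()
            p.flat[i] = orig - eps
            lm = loss()
            p.flat[i] = orig
            num = (lp - lm) / (2 * eps)
            ana = layer.grads[k].flat[i]
            assert abs(num - ana) / max(floor, abs(num) + abs(ana)) < tol, (
                layer.name, k, i, num, ana,
            )
    for i in rng.choice(x.size, size=6, replace=False):
        orig = x.flat[i]
        x.flat[i] = orig + eps
        lp = loss()
        x.flat[i] = orig - eps
        lm = loss()
        x.flat[i] = orig
        num = (lp - lm) / (2 * eps)
        ana = gin.flat[i]
        assert abs(num - ana) / max(floor, abs(num) + abs(ana)) < tol


class TestLayerGradients:
    def test_conv(self):
        rng = np.random.default_rng(0)
        _fd_check(Conv2D("c", 3, 4, rng), rng.random((2, 6, 6, 3)).astype(np.float32))

    def test_batchnorm_train_and_eval(self):
        rng = np.random.default_rng(1)
        x = rng.random((2, 5, 5, 3)).astype(np.float32) + 0.5
        # train-mode input grads couple every element through the batch
        # statistics; float32 finite differences are noisier there
        _fd_check(BatchNorm("bn", 3), x.copy(), train=True, tol=2e-2, floor=0.05)
        _fd_check(BatchNorm("bn2", 3), x.copy(), train=False)

    @pytest.mark.parametrize("stride", [1, 2])
    def test_maxpool(self, stride):
        rng = np.random.default_rng(2)
        # distinct values avoid tie subgradient ambiguity in the check
        x = rng.permutation(np.arange(2 * 6 * 6 * 3, dtype=np.float32)).reshape(
            2, 6, 6, 3
        ) / 10.0
        _fd_check(MaxPool2D("p", 2, stride), x)

    def test_dense(self):
        rng = np.random.default_rng(3)
        _fd_check(Dense("d", 5, 4, rng, "relu"),
                  rng.standard_normal((3, 5)).astype(np.float32))

    def test_lstm(self):
        rng = np.random.default_rng(4)
        layer = LSTM("l", 5, 6, rng, dropout=0.0, recurrent_dropout=0.0)
        _fd_check(layer, rng.standard_normal((2, 4, 5)).astype(np.float32))


class TestBuildModel:
    def test_published_layer_param_counts(self):
        model = build_model(ModelSpec())
        counts = model.layer_param_counts()
        assert counts["block1_conv1"] == 3 * 3 * 3 * 8 + 8  # = 224
        assert counts["block1_conv2"] == 3 * 3 * 8 * 4 + 4
        assert counts["block2_conv1"] == 3 * 3 * 4 * 16 + 16
        assert counts["block2_conv2"] == 3 * 3 * 16 * 8 + 8
        assert counts["block3_conv1"] == 3 * 3 * 8 * 32 + 32
        assert counts["block3_conv2"] == 3 * 3 * 32 * 16 + 16
        assert counts["block4_conv1"] == 3 * 3 * 16 * 64 + 64
        # stride-1 2x2 pooling: each block shrinks the grid by one pixel
        assert model.feature_hw == (97, 97, 64)
        d = 97 * 97 * 64
        assert counts["lstm"] == 4 * 100 * (d + 100 + 1)
        assert counts["dense"] == 100 * 100 + 100
        assert counts["head"] == 100 * 2 + 2

    def test_softmax_contract_untrained(self):
        model = build_model(TINY_SPEC)
        x = np.random.default_rng(0).random((4, 3, 10, 10, 3)).astype(np.float32)
        p = _softmax(model.forward_logits(x))
        assert np.all(p >= 0)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_wrong_frame_count_rejected(self):
        model = build_model(TINY_SPEC)
        bad = np.zeros((1, 5, 10, 10, 3), dtype=np.float32)
        with pytest.raises(InputShapeError):
            model.forward_logits(bad)

    def test_unknown_layer_name(self):
        model = build_model(TINY_SPEC)
        with pytest.raises(LayerNotFoundError):
            model.layer("block9_conv9")

    def test_gradcam_target_is_penultimate_block(self):
        assert ModelSpec().penultimate_conv1 == "block3_conv1"


class TestSplitDataset:
    def test_100_videos_80_10_10(self):
        videos = _toy_videos(100, None)
        tr, va, te = split_dataset(videos, TrainConfig(seed=0))
        assert (len(tr), len(va), len(te)) == (80, 10, 10)
        ids = sorted(v.cell_id for part in (tr, va, te) for v in part)
        assert ids == list(range(100))

    def test_10_videos_8_1_1(self):
        videos = _toy_videos(10, None)
        tr, va, te = split_dataset(videos, TrainConfig(seed=1))
        assert (len(tr), len(va), len(te)) == (8, 1, 1)

    def test_stratified(self):
        videos = _toy_videos(100, None)
        tr, va, te = split_dataset(videos, TrainConfig(seed=2))
        for part, n in ((tr, 40), (va, 5), (te, 5)):
            assert sum(v.label == "cognate" for v in part) == n

    def test_deterministic_under_seed(self):
        videos = _toy_videos(40, None)
        a = split_dataset(videos, TrainConfig(seed=5))
        b = split_dataset(videos, TrainConfig(seed=5))
        for pa, pb in zip(a, b):
            assert [v.cell_id for v in pa] == [v.cell_id for v in pb]

    def test_single_class_rejected(self):
        videos = [v for v in _toy_videos(20, None) if v.label == "cognate"]
        with pytest.raises(StratificationError):
            split_dataset(videos, TrainConfig())


class TestAugment:
    def test_zero_shift_identity(self):
        video = _toy_videos(1, None)[0]
        rng = np.random.default_rng(0)
        out = augment(video, 0, rng)
        assert np.array_equal(out.data, video.data)

    def test_pixel_count_conserved_inside(self):
        video = _toy_videos(1, None)[0]

        class FixedRng:
            def integers(self, lo, hi, n):
                return np.array([5, 0])

        out = augment(video, 5, FixedRng())
        assert out.data.sum() == video.data.sum()  # nothing shifted out
        assert np.array_equal(out.data[:, :, 5:, :].sum(), video.data[:, :, :-5, :].sum())

    def test_binary_preserved(self):
        video = _toy_videos(1, None)[0]
        out = augment(video, 4, np.random.default_rng(3))
        assert set(np.unique(out.data)) <= {0, 1}

    def test_same_shift_all_frames(self):
        video = _toy_videos(1, None)[0]
        out = augment(video, 4, np.random.default_rng(5))
        ref = out.data[0]
        base = video.data[0]
        # all frames experienced the same displacement
        for f in range(video.n_frames):
            assert np.array_equal(out.data[f] - ref, video.data[f] - base)


class TestDownsample:
    def test_binary_and_shape(self):
        data = np.zeros((2, 101, 101, 3), dtype=np.uint8)
        data[:, 50, 50, 1] = 1
        out = downsample_video(data, 6)
        assert out.shape == (2, 17, 17, 3)
        assert set(np.unique(out)) <= {0, 1}
        assert out[:, 8, 8, 1].all()  # the lone pixel survives max-pooling

    def test_factor_one_identity(self):
        data = np.zeros((1, 10, 10, 3), dtype=np.uint8)
        assert downsample_video(data, 1) is data


class TestTrainingSmall:
    """Fast optimization sanity checks on a tiny separable problem."""

    @pytest.fixture(scope="class")
    def toy_data(self):
        videos = _toy_videos(24, None, frames=3, size=10)
        x, y = videos_to_arrays(videos)
        return x, y

    def test_loss_decreases_and_deterministic(self, toy_data):
        x, y = toy_data
        cfg = TrainConfig(epochs=5, seed=0, batch_size=8, augment=False)
        spec = dataclasses.replace(TINY_SPEC, learning_rate=1e-3)
        m1, h1 = train_model(build_model(spec), (x, y), (x, y), cfg)
        assert h1["loss"][-1] <= h1["loss"][0]
        m2, h2 = train_model(build_model(spec), (x, y), (x, y), cfg)
        assert h1 == h2  # identical histories under identical seeds
        np.testing.assert_array_equal(m1.predict_proba(x), m2.predict_proba(x))

    def test_nan_abort(self, toy_data):
        x, y = toy_data
        spec = dataclasses.replace(TINY_SPEC, learning_rate=1e30)
        from tcelldc.errors import TrainingDivergedError

        with pytest.raises(TrainingDivergedError):
            train_model(
                build_model(spec), (x, y), (x, y),
                TrainConfig(epochs=8, seed=0, batch_size=8, augment=False),
            )

    def test_save_load_bit_identical(self, toy_data, tmp_path):
        x, y = toy_data
        cfg = TrainConfig(epochs=2, seed=1, batch_size=8, augment=False)
        spec = dataclasses.replace(TINY_SPEC, learning_rate=1e-3)
        model, _ = train_model(build_model(spec), (x, y), (x, y), cfg)
        path = tmp_path / "model.npz"
        save_model(model, path)
        again = load_model(path)
        np.testing.assert_array_equal(
            model.predict_proba(x), again.predict_proba(x)
        )
        assert again.spec == model.spec

    def test_duplicated_video_same_probability(self, toy_data):
        x, y = toy_data
        model = build_model(TINY_SPEC.__class__(
            input_shape=x.shape[1:],
            conv_blocks=TINY_SPEC.conv_blocks,
            lstm_units=8, dense_units=6, init_seed=0,
        ))
        x2 = np.concatenate([x[:1], x[:1]])
        p = model.predict_proba(x2)
        assert p[0] == p[1]
        assert np.all((p >= 0) & (p <= 1))


class TestGradCamSmall:
    def test_shapes_and_range(self):
        model = build_model(TINY_SPEC)
        video = np.random.default_rng(0).random((3, 10, 10, 3)).astype(np.float32)
        cam = grad_cam(model, video, class_index=1, out_px=101)
        assert cam.maps.shape == (3, 101, 101)
        assert cam.maps.min() >= 0.0
        assert cam.maps.max() <= 1.0 + 1e-6
        assert cam.target_layer == "block3_conv1"

    def test_zero_input_zero_or_uniform(self):
        model = build_model(TINY_SPEC)
        video = np.zeros((3, 10, 10, 3), dtype=np.float32)
        cam = grad_cam(model, video)
        assert cam.maps.max() <= 1.0 + 1e-6
        assert cam.maps.min() >= 0.0

    def test_missing_layer_errors(self):
        model = build_model(TINY_SPEC)
        video = np.zeros((3, 10, 10, 3), dtype=np.float32)
        with pytest.raises(LayerNotFoundError):
            grad_cam(model, video, target_layer="nope")
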