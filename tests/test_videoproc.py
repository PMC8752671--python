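import numpy as np
import pytest

from tcelldc.errors import CropSizingError, FrameExclusionError
from tcelldc.params import Condition, PipelineParams, SimParams
from tcelldc.simulator import simulate_field
from tcelldc.videoproc import (
    binarize,
    crop_window,
    field_dc_threshold,
    huang_threshold,
    mask_neighbors,
    otsu_threshold,
    process_cell,
    process_field,
    sample_frames,
)

# ---------------------------------------------------------------------------
# brute-force threshold oracles (independent of the implementations)
# ---------------------------------------------------------------------------


def brute_force_otsu(hist):
    """Maximize between-class variance by scanning all 256 cut levels."""
    hist = np.asarray(hist, dtype=float)
    levels = np.arange(256)
    best_t, best_v = None, -1.0
    for t in range(256):
        w0 = hist[: t + 1].sum()
        w1 = hist[t + 1 :].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[: t + 1] * levels[: t + 1]).sum() / w0
        mu1 = (hist[t + 1 :] * levels[t + 1 :]).sum() / w1
        v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return best_t


def brute_force_huang(hist):
    """Naive per-threshold fuzzy-entropy computation (no cumulative sums)."""
    hist = np.asarray(hist, dtype=float)
    nz = np.nonzero(hist)[0]
    first, last = nz[0], nz[-1]
    if first == last:
        return int(first)
    c = float(last - first)
    entropies = {}
    for t in range(first, last):
        n0 = hist[: t + 1].sum()
        n1 = hist[t + 1 :].sum()
        if n0 == 0 or n1 == 0:
            continue
        mu0 = sum(g * hist[g] for g in range(t + 1)) / n0
        mu1 = sum(g * hist[g] for g in range(t + 1, 256)) / n1
        s = 0.0
        for g in range(256):
            if hist[g] == 0:
                continue
            mu = mu0 if g <= t else mu1
            u = 1.0 / (1.0 + abs(g - mu) / c)
            if 0.0 < u < 1.0:
                s += hist[g] * (-u * np.log(u) - (1 - u) * np.log(1 - u))
        entropies[t] = s
    s_min = min(entropies.values())
    plateau = [t for t, s in entropies.items() if s <= s_min + 1e-12]
    return plateau[len(plateau) // 2]


class TestCropWindow:
    def test_centered_window(self):
        assert crop_window((300, 200), (512, 512), 101) == (150, 251, 250, 351)

    def test_clamped_left_edge(self):
        assert crop_window((300, 10), (512, 512), 101) == (0, 101, 250, 351)

    def test_clamped_max_corner(self):
        assert crop_window((511, 511), (512, 512), 101) == (411, 512, 411, 512)

    def test_window_always_full_size(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            h, w = rng.integers(101, 400, 2)
            x = rng.uniform(0, w - 1)
            y = rng.uniform(0, h - 1)
            r0, r1, c0, c1 = crop_window((x, y), (h, w), 101)
            assert r1 - r0 == 101 and c1 - c0 == 101
            assert 0 <= r0 and r1 <= h and 0 <= c0 and c1 <= w

    def test_rounding_ties_toward_larger(self):
        r0, r1, c0, c1 = crop_window((200.5, 300.5), (512, 512), 101)
        assert (r0, c0) == (301 - 50, 201 - 50)

    def test_field_too_small(self):
        with pytest.raises(CropSizingError):
            crop_window((10, 10), (100, 100), 101)


class TestThresholds:
    def test_otsu_matches_bruteforce_random(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            hist = rng.integers(0, 50, 256)
            hist[rng.integers(0, 256, 10)] += rng.integers(100, 1000, 10)
            if hist.sum() == 0:
                continue
            assert otsu_threshold(hist) == brute_force_otsu(hist)

    def test_huang_matches_bruteforce_random(self):
        rng = np.random.default_rng(43)
        for _ in range(100):
            hist = np.zeros(256, dtype=int)
            # bimodal-ish random histograms
            for mu, s, n in ((rng.integers(10, 100), 10, 500),
                             (rng.integers(120, 240), 15, 500)):
                vals = np.clip(rng.normal(mu, s, n).astype(int), 0, 255)
                hist += np.bincount(vals, minlength=256)
            assert huang_threshold(hist) == brute_force_huang(hist)

    def test_huang_two_delta_symmetric(self):
        hist = np.zeros(256, dtype=int)
        hist[50] = 1000
        hist[200] = 1000
        t = huang_threshold(hist)
        assert 50 < t < 200
        mirrored = hist[::-1]
        tm = huang_threshold(mirrored)
        # inversion maps cut t to 255 - t - 1 on the mirrored histogram
        assert abs((255 - t - 1) - tm) <= 1

    def test_huang_single_delta_degenerate(self):
        hist = np.zeros(256, dtype=int)
        hist[77] = 123
        assert huang_threshold(hist) == 77

    def test_huang_uniform_equals_oracle(self):
        hist = np.full(256, 10)
        assert huang_threshold(hist) == brute_force_huang(hist)

    def test_otsu_bimodal_between_peaks(self):
        hist = np.zeros(256, dtype=int)
        hist[10] = 400
        hist[200] = 600
        assert 10 <= otsu_threshold(hist) < 200

    def test_empty_histogram_rejected(self):
        with pytest.raises(ValueError):
            huang_threshold(np.zeros(256))
        with pytest.raises(ValueError):
            otsu_threshold(np.zeros(256))


class TestSampleFrames:
    @pytest.mark.parametrize(
        "n,expected",
        [
            (20, list(range(20))),
            (39, list(range(20))),
            (45, list(range(0, 40, 2))),
            (40, list(range(0, 40, 2))),
            (59, list(range(0, 40, 2))),
            (61, list(range(0, 60, 3))),
            (60, list(range(0, 60, 3))),
            (120, list(range(0, 60, 3))),
        ],
    )
    def test_uniform_rules(self, n, expected):
        assert sample_frames(n, "uniform") == expected

    def test_uniform_excludes_below_20(self):
        with pytest.raises(FrameExclusionError):
            sample_frames(19, "uniform")

    def test_uniform_property_exhaustive(self):
        for n in range(20, 201):
            idx = sample_frames(n, "uniform")
            assert len(idx) == 20
            assert idx[0] == 0
            assert all(b > a for a, b in zip(idx, idx[1:]))
            assert idx[-1] < n

    @pytest.mark.parametrize("k", [2, 5, 10, 20])
    def test_consecutive(self, k):
        assert sample_frames(45, "consecutive_k", k) == list(range(k))

    def test_consecutive_insufficient(self):
        with pytest.raises(FrameExclusionError):
            sample_frames(3, "consecutive_k", 5)


class TestMaskNeighbors:
    def test_two_cell_frame_keeps_center(self):
        frame = np.zeros((1, 101, 101, 3), dtype=np.uint8)
        frame[0, 45:56, 45:56, 1] = 200  # centered cell
        frame[0, 5:16, 5:16, 1] = 200    # neighbor
        roi = np.zeros((101, 101), dtype=bool)
        roi[40:61, 40:61] = True
        out = mask_neighbors(frame, [roi])
        assert out[0, 50, 50, 1] == 200
        assert not out[0, :20, :20, 1].any()
        n_before = np.count_nonzero(frame[0, :, :, 1])
        assert np.count_nonzero(out[0, :, :, 1]) == n_before - 121

    def test_full_roi_is_identity(self):
        frame = np.random.default_rng(0).integers(
            0, 255, (2, 50, 50, 3)
        ).astype(np.uint8)
        roi = np.ones((50, 50), dtype=bool)
        assert np.array_equal(mask_neighbors(frame, [roi, roi]), frame)

    def test_empty_roi_blanks_channel1_only(self):
        frame = np.full((1, 30, 30, 3), 100, dtype=np.uint8)
        out = mask_neighbors(frame, [np.zeros((30, 30), dtype=bool)])
        assert not out[0, :, :, 1].any()
        assert (out[0, :, :, 0] == 100).all()

    def test_masking_never_increases_pixels(self):
        rng = np.random.default_rng(1)
        frame = rng.integers(0, 255, (3, 40, 40, 3)).astype(np.uint8)
        rois = [rng.random((40, 40)) > 0.5 for _ in range(3)]
        out = mask_neighbors(frame, rois)
        assert np.count_nonzero(out[..., 1]) <= np.count_nonzero(frame[..., 1])


class TestBinarize:
    def test_all_zero_dc_channel(self):
        cropped = np.zeros((2, 101, 101, 3), dtype=np.uint8)
        cropped[..., 1] = 0
        out = binarize(cropped, dc_threshold=np.inf)
        assert not out.any()

    def test_binary_output_and_idempotence(self):
        p = SimParams(seed=4, n_frames=20, n_tcells=1, n_dcs=1, noise_sd=0.0)
        stack, gt = simulate_field(p, Condition("cognate"))
        video = process_cell(stack, gt.tracks[0])
        assert set(np.unique(video.data)) <= {0, 1}
        # re-binarizing a binary video leaves foreground where threshold allows
        again = binarize(video.data.astype(np.uint8), dc_threshold=0.5,
                         blur_sigma=0.0)
        assert np.array_equal(again[..., 0], video.data[..., 0])

    def test_mask_matches_rendered_shape(self):
        p = SimParams(seed=5, n_frames=20, n_tcells=1, n_dcs=0, noise_sd=0.0)
        stack, gt = simulate_field(p, Condition("non-cognate"))
        video = process_cell(stack, gt.tracks[0])
        # single free cell: binarized T mask area close to rendered ellipse area
        for f in range(video.n_frames):
            area = video.data[f, :, :, 1].sum()
            rendered = np.count_nonzero(stack.data[f, :, :, 1] > 100)
            assert abs(area - rendered) <= np.pi * 2 * p.tcell_radius * 2  # blur halo


class TestProcessCell:
    def test_shape_and_provenance(self, small_field):
        params, stack, gt = small_field
        video = process_cell(stack, gt.tracks[0])
        assert video.data.shape == (20, 101, 101, 3)
        assert not video.data[..., 2].any()
        assert video.provenance["sampling_mode"] == "uniform"
        assert len(video.provenance["source_frames"]) == 20

    def test_deterministic(self, small_field):
        _, stack, gt = small_field
        a = process_cell(stack, gt.tracks[1])
        b = process_cell(stack, gt.tracks[1])
        assert np.array_equal(a.data, b.data)

    def test_short_track_excluded_by_field_processing(self, small_field):
        import dataclasses

        _, stack, gt = small_field
        short = dataclasses.replace(
            gt.tracks[0], points=gt.tracks[0].points[:10], cell_id=99
        )
        videos = process_field(stack, [short] + list(gt.tracks[1:3]))
        assert all(v.cell_id != 99 for v in videos)
        assert len(videos) == 2

    def test_consecutive_mode(self, small_field):
        _, stack, gt = small_field
        params = PipelineParams(sampling_mode="consecutive_k", consecutive_k=5)
        video = process_cell(stack, gt.tracks[0], params)
        assert video.n_frames == 5
        assert video.provenance["source_frames"] == [0, 1, 2, 3, 4]

    def test_field_threshold_shared(self, small_field):
        _, stack, gt = small_field
        t = field_dc_threshold(stack)
        a = process_cell(stack, gt.tracks[0], dc_threshold=t)
        assert a.provenance["dc_threshold"] == pytest.approx(t)
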