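import numpy as np
import pytest
from scipy.ndimage import fourier_shift, gaussian_filter

from whitefront import (
    Calibration,
    ScenarioParams,
    TrackConfig,
    difference_image,
    locate_front,
    register_pair,
    segment_whitening,
    select_whitening_region,
    sync_frames,
    synth_video,
    track,
)
from whitefront.tracking import RigidShift, apply_join_operator

CAL = Calibration(mm_per_pixel=0.01)


def _texture(seed=0, n=64):
    rng = np.random.default_rng(seed)
    return gaussian_filter(rng.normal(size=(n, n)), 1.2)


def _fourier_shifted(img, dy, dx):
    return np.fft.ifftn(fourier_shift(np.fft.fftn(img), (dy, dx))).real


# ---------------------------------------------------------------- morphology oracle
DISK2_OFFSETS = [(0, 0), (1, 0), (-1, 0), (0, 1), (0, -1)]  # 2-px-diameter disc


def brute_dilate(mask, offsets=DISK2_OFFSETS):
    out = np.zeros_like(mask)
    for dy, dx in offsets:
        shifted = np.zeros_like(mask)
        src = mask[
            max(0, -dy) : mask.shape[0] - max(0, dy),
            max(0, -dx) : mask.shape[1] - max(0, dx),
        ]
        shifted[
            max(0, dy) : mask.shape[0] - max(0, -dy),
            max(0, dx) : mask.shape[1] - max(0, -dx),
        ] = src
        out |= shifted
    return out


def brute_erode(mask, offsets=DISK2_OFFSETS):
    # complement duality on the infinite plane (background outside the array)
    pad = np.pad(mask, 2, constant_values=False)
    out = ~brute_dilate(~pad, [(-dy, -dx) for dy, dx in offsets])
    return out[2:-2, 2:-2]


def brute_closing(mask):
    pad = np.pad(mask, 3, constant_values=False)
    return brute_erode(brute_dilate(pad))[3:-3, 3:-3]


def brute_opening(mask):
    pad = np.pad(mask, 3, constant_values=False)
    return brute_dilate(brute_erode(pad))[3:-3, 3:-3]


class TestRegisterPair:
    def test_self_registration_is_zero(self):
        img = _texture()
        s = register_pair(img, img)
        assert (s.dy, s.dx) == (0.0, 0.0)
        assert s.peak_corr > 0.99

    def test_subpixel_shift_recovered(self):
        ref = _texture(3)
        cur = _fourier_shifted(ref, 3.25, -1.5)
        s = register_pair(ref, cur, upsample_factor=100)
        assert abs(s.dy - 3.25) < 0.05
        assert abs(s.dx + 1.5) < 0.05

    def test_integer_shift_matches_brute_force_argmax(self):
        ref = _texture(4, n=32)
        cur = np.roll(ref, (5, -2), axis=(0, 1))
        # oracle: argmax of the full circular cross-correlation
        cc = np.fft.ifftn(np.fft.fftn(cur) * np.conj(np.fft.fftn(ref))).real
        peak = np.unravel_index(np.argmax(cc), cc.shape)
        dy = peak[0] if peak[0] <= 16 else peak[0] - 32
        dx = peak[1] if peak[1] <= 16 else peak[1] - 32
        assert (dy, dx) == (5, -2)
        s = register_pair(ref, cur, upsample_factor=1)
        assert (s.dy, s.dx) == (5.0, -2.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="texture"):
            register_pair(np.zeros((16, 16)), _texture(0, 16))

    @pytest.mark.parametrize("seed", range(5))
    def test_registration_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        dy, dx = rng.uniform(-5, 5, 2)
        ref = _texture(seed + 10)
        s = register_pair(ref, _fourier_shifted(ref, dy, dx), upsample_factor=100)
        assert np.hypot(s.dy - dy, s.dx - dx) < 0.05


class TestDifferenceImage:
    def test_identical_frames_give_zero(self):
        img = _texture()
        d = difference_image(img, img, RigidShift(0.0, 0.0))
        assert np.all(d == 0.0)

    def test_additive_blob_recovered(self):
        ref = np.full((32, 32), 0.4)
        cur = ref.copy()
        cur[10:15, 10:15] += 0.2
        d = difference_image(ref, cur, RigidShift(0.0, 0.0))
        np.testing.assert_allclose(d[10:15, 10:15], 0.2, atol=1e-12)
        assert d.sum() == pytest.approx(0.2 * 25)

    def test_pure_jitter_cancels(self):
        ref = 0.5 + 0.2 * _texture(5)
        dy, dx = 0.6, -0.4
        cur = _fourier_shifted(ref, dy, dx)
        s = register_pair(ref, cur, upsample_factor=100)
        d = difference_image(ref, cur, s)
        assert d[3:-3, 3:-3].max() < 0.02  # below any plausible noise floor

    def test_negative_changes_clipped(self):
        ref = np.full((8, 8), 0.5)
        cur = np.full((8, 8), 0.3)
        d = difference_image(ref, cur, RigidShift(0.0, 0.0))
        assert np.all(d == 0.0)


class TestSegmentWhitening:
    def test_zero_difference_empty_mask(self):
        wm = segment_whitening(np.zeros((16, 16)), 0.5)
        assert not wm.mask.any()

    def test_closing_joins_across_one_pixel_gap(self):
        diff = np.zeros((12, 16))
        diff[4:7, 3:6] = 1.0
        diff[4:7, 7:10] = 1.0  # 1-px dark gap at col 6
        wm = segment_whitening(diff, 0.5, 2, "closing")
        np.testing.assert_array_equal(wm.mask, brute_closing(diff >= 0.5))
        from skimage.measure import label

        assert label(wm.mask, connectivity=1).max() == 1

    def test_opening_removes_isolated_pixel(self):
        diff = np.zeros((10, 10))
        diff[5, 5] = 1.0
        wm = segment_whitening(diff, 0.5, 2, "opening")
        np.testing.assert_array_equal(wm.mask, brute_opening(diff >= 0.5))
        assert not wm.mask.any()

    def test_min_area_removes_specks(self):
        diff = np.zeros((20, 20))
        diff[2, 2] = 1.0  # single speck survives closing
        diff[10:14, 10:14] = 1.0
        wm = segment_whitening(diff, 0.5, 2, "closing", min_area_px=5)
        assert not wm.mask[2, 2]
        assert wm.mask[10:14, 10:14].all()

    def test_threshold_bounds_enforced(self):
        with pytest.raises(ValueError):
            segment_whitening(np.zeros((4, 4)), 0.0)

    @pytest.mark.parametrize("operator", ["closing", "opening"])
    @pytest.mark.parametrize("seed", range(10))
    def test_morphology_matches_brute_force(self, operator, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((32, 32)) < 0.35
        got = apply_join_operator(mask, 2, operator)
        want = brute_closing(mask) if operator == "closing" else brute_opening(mask)
        np.testing.assert_array_equal(got, want)


class TestLocateFront:
    def test_single_pixel_at_tip_zero_displacement(self):
        mask = np.zeros((32, 32), bool)
        mask[20, 16] = True
        fp = locate_front(mask, (20, 16), CAL)
        assert fp.displacement_mm == 0.0

    def test_vertical_bar_displacement(self):
        mask = np.zeros((64, 32), bool)
        mask[10:61, 16] = True  # rises 50 px above the tip at row 60
        fp = locate_front(mask, (60, 16), CAL)
        assert fp.displacement_mm == pytest.approx(0.50)

    def test_farther_extremum_chosen(self):
        mask = np.zeros((32, 64), bool)
        mask[5, 10] = True
        mask[5, 40] = True
        fp = locate_front(mask, (20, 10), CAL, displacement_mode="euclidean")
        assert fp.pixel == (5, 40)
        assert fp.displacement_mm == pytest.approx(np.hypot(15, 30) * 0.01)

    def test_tie_breaks_to_top_left(self):
        mask = np.zeros((32, 64), bool)
        mask[5, 10] = True
        mask[5, 30] = True
        fp = locate_front(mask, (20, 20), CAL)
        assert fp.pixel == (5, 10)

    def test_empty_mask_returns_none(self):
        assert locate_front(np.zeros((8, 8), bool), (4, 4), CAL) is None

    def test_largest_component_selection(self):
        mask = np.zeros((32, 32), bool)
        mask[20:25, 14:19] = True
        mask[2, 2] = True  # speck far above must not win
        region = select_whitening_region(mask)
        assert not region[2, 2]
        assert region[20:25, 14:19].all()


class TestTrack:
    def _static_scenario(self):
        return ScenarioParams(seed=5, n_frames=30, onset_frame=25,
                              breakthrough_frame=28, halo_amplitude=0.0,
                              noise_sd=0.0, jitter_sd_px=0.0)

    def test_static_video_yields_zero_displacement(self):
        p = self._static_scenario()
        frames, gt = synth_video(p)
        synced = sync_frames(frames, gt.mech)
        traj = track(frames, synced, p.notch_tip_px, p.calibration,
                     TrackConfig(roi=p.roi()))
        assert np.all(np.isnan(traj.da_raw_mm) | (traj.da_raw_mm == 0.0))
        assert np.all(traj.da_mono_mm == 0.0)

    def test_programmed_slope_recovered(self, tracked_scenario):
        """Front rising ~0.92 px/frame must be recovered within 0.5 px RMS."""
        params, frames, truth, synced, traj = tracked_scenario
        sel = slice(params.onset_frame, params.breakthrough_frame)
        raw_px = traj.da_raw_mm[sel] / params.mm_per_pixel
        true_px = truth.da_true_mm[sel] / params.mm_per_pixel
        assert np.sqrt(np.nanmean((raw_px - true_px) ** 2)) < 0.5

    def test_monotonicised_series_is_running_max(self, tracked_scenario):
        *_, traj = tracked_scenario
        running = 0.0
        for raw, mono in zip(traj.da_raw_mm, traj.da_mono_mm):
            if np.isfinite(raw):
                running = max(running, raw)
            assert mono == running

    def test_displacements_non_negative_and_mono_non_decreasing(self, tracked_scenario):
        *_, traj = tracked_scenario
        finite = traj.da_raw_mm[np.isfinite(traj.da_raw_mm)]
        assert np.all(finite >= 0.0)
        assert np.all(np.diff(traj.da_mono_mm) >= 0.0)

    def test_dropout_frame_does_not_reverse_monotone_series(self):
        # fabricate a trajectory-like raw series with a dropout: running max holds
        raw = np.array([0.0, 1.0, np.nan, 2.0])
        running, mono = 0.0, []
        for r in raw:
            if np.isfinite(r):
                running = max(running, r)
            mono.append(running)
        assert mono == [0.0, 1.0, 1.0, 2.0]

    def test_visible_crack_line_does_not_disturb_front(self):
        """Dark crack inside the whitening zone is closed over (rat preset)."""
        from whitefront import rat_tibia_scenario

        p = rat_tibia_scenario(seed=2, crack_lag_mm=0.35)
        frames, gt = synth_video(p)
        synced = sync_frames(frames, gt.mech)
        traj = track(frames, synced, p.notch_tip_px, p.calibration,
                     TrackConfig(roi=p.roi(), reg_window=p.reg_window()))
        truth = np.where(np.isfinite(gt.front_px[:, 0]), gt.da_true_mm, 0.0)
        raw = np.where(np.isfinite(traj.da_raw_mm), traj.da_raw_mm, 0.0)
        rms_px = np.sqrt(np.mean(((raw - truth) / p.mm_per_pixel) ** 2))
        assert rms_px <= 2.0
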