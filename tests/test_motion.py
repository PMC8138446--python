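"""Exhaustive-search block matching and motion-based beat rate."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from liverheart.motion import (
    VideoStack,
    block_match,
    motion_series,
    beat_rate_from_motion,
)
from liverheart.synthetic import VideoSpec, make_contraction_video


def texture(shape=(48, 48), seed=0):
    rng = np.random.default_rng(seed)
    return rng.random(shape)


class TestBlockMatch:
    def test_identical_frames_zero_displacement(self):
        a = texture()
        mf = block_match(a, a, search_radius=4)
        assert np.all(mf.dy[mf.valid] == 0.0)
        assert np.all(mf.dx[mf.valid] == 0.0)
        assert np.all(mf.cost[mf.valid] == 0.0)

    def test_integer_shift_recovered_exactly(self):
        a = texture()
        dy, dx = 3, 2
        b = np.roll(a, (dy, dx), axis=(0, 1))
        mf = block_match(a, b, search_radius=5)
        # interior blocks (whose true target stays inside the frame)
        interior = np.ones_like(mf.dy, dtype=bool)
        interior[0, :] = interior[-1, :] = False
        interior[:, 0] = interior[:, -1] = False
        sel = interior & mf.valid
        assert np.all(mf.dy[sel] == dy)
        assert np.all(mf.dx[sel] == dx)
        assert np.all(mf.cost[sel] == 0.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        dy=st.integers(-4, 4), dx=st.integers(-4, 4), seed=st.integers(0, 50)
    )
    def test_shift_recovery_property(self, dy, dx, seed):
        """Bit-exact recovery for any integer shift within the radius."""
        a = texture(seed=seed)
        b = np.roll(a, (dy, dx), axis=(0, 1))
        mf = block_match(a, b, search_radius=4)
        interior = np.zeros_like(mf.dy, dtype=bool)
        interior[1:-1, 1:-1] = True
        sel = interior & mf.valid
        assert np.all(mf.dy[sel] == dy) and np.all(mf.dx[sel] == dx)

    def test_symmetry_under_frame_exchange(self):
        a = texture(seed=3)
        b = np.roll(a, (2, -3), axis=(0, 1))
        fwd = block_match(a, b, search_radius=4)
        bwd = block_match(b, a, search_radius=4)
        interior = np.zeros_like(fwd.dy, dtype=bool)
        interior[1:-1, 1:-1] = True
        assert np.all(fwd.dy[interior] == -bwd.dy[interior])
        assert np.all(fwd.dx[interior] == -bwd.dx[interior])

    def test_reported_cost_is_the_minimum(self):
        """Direct assertion of the exhaustive-search contract: no candidate
        displacement beats the reported one."""
        rng = np.random.default_rng(7)
        a = rng.random((32, 32))
        b = rng.random((32, 32))
        radius, bs = 3, 8
        mf = block_match(a, b, search_radius=radius, block_size=bs)
        ys = np.arange(0, 32 - bs + 1, bs)
        xs = np.arange(0, 32 - bs + 1, bs)
        for iy, y in enumerate(ys):
            for ix, x in enumerate(xs):
                block = a[y:y + bs, x:x + bs]
                for dy in range(-radius, radius + 1):
                    for dx in range(-radius, radius + 1):
                        ty, tx = y + dy, x + dx
                        if not (0 <= ty <= 32 - bs and 0 <= tx <= 32 - bs):
                            continue
                        cost = np.abs(block - b[ty:ty + bs, tx:tx + bs]).sum()
                        assert mf.cost[iy, ix] <= cost + 1e-9

    def test_shift_beyond_radius_clamped_and_flagged(self):
        # a monotone (gradient) texture makes the SAD landscape decrease
        # toward the true shift, so the constrained minimum provably sits
        # on the window edge
        a = np.tile(np.arange(48.0), (48, 1))
        b = np.roll(a, (0, 6), axis=(0, 1))
        mf = block_match(a, b, search_radius=3)
        interior = np.zeros_like(mf.dy, dtype=bool)
        interior[1:-1, 1:-1] = True
        sel = interior & mf.valid
        assert np.all(mf.dx[sel] == 3)
        assert np.all(mf.clamped[sel])
        assert np.all(mf.cost[sel] > 0)

    def test_low_texture_blocks_missing(self):
        a = np.zeros((32, 32))
        mf = block_match(a, a, search_radius=3)
        assert not mf.valid.any()
        assert np.all(np.isnan(mf.dy))

    def test_frame_smaller_than_block_rejected(self):
        with pytest.raises(ValueError):
            block_match(np.zeros((4, 4)), np.zeros((4, 4)), block_size=8)


class TestMotionSeries:
    def test_static_video_is_silent(self):
        frames = np.broadcast_to(texture((32, 32)), (10, 32, 32)).copy()
        video = VideoStack(frames, 50.0)
        s = motion_series(video, frame_lag=5, search_radius=3)
        assert np.allclose(s, 0.0)
        assert np.isnan(beat_rate_from_motion(s, 50.0, 5))

    def test_lag_must_be_shorter_than_video(self):
        video = VideoStack(np.zeros((8, 16, 16)), 50.0)
        with pytest.raises(ValueError):
            motion_series(video, frame_lag=8)

    def test_speed_peaks_twice_per_cycle(self):
        """A 2-s period gives contraction/relaxation speed peaks 1.0 s apart."""
        spec = VideoSpec(period_s=2.0, frame_rate_hz=50.0)
        video, _ = make_contraction_video(spec, 6.0)
        s = motion_series(video, frame_lag=5, search_radius=5)
        from scipy.ndimage import gaussian_filter1d
        from scipy.signal import find_peaks

        smooth = gaussian_filter1d(s, 5.0)
        peaks, _ = find_peaks(smooth, prominence=0.5 * np.ptp(smooth))
        spacing = np.diff(peaks) / spec.frame_rate_hz
        assert np.allclose(spacing, 1.0, atol=0.15)


class TestBeatRate:
    def test_thirty_bpm_recovered(self):
        spec = VideoSpec(period_s=2.0, frame_rate_hz=50.0)
        video, _ = make_contraction_video(spec, 6.0)
        s = motion_series(video, frame_lag=5, search_radius=5)
        bpm = beat_rate_from_motion(s, spec.frame_rate_hz, 5)
        assert bpm == pytest.approx(30.0, abs=1.0)

    def test_frame_rate_invariance(self):
        rates = []
        for fps in (50.0, 100.0):
            spec = VideoSpec(period_s=2.0, frame_rate_hz=fps)
            video, _ = make_contraction_video(spec, 6.0)
            s = motion_series(video, frame_lag=5, search_radius=5)
            rates.append(beat_rate_from_motion(s, fps, 5))
        assert rates[0] == pytest.approx(rates[1], abs=1.0)

    def test_too_few_peaks_missing(self):
        assert np.isnan(beat_rate_from_motion(np.array([0.0, 1.0, 0.0]), 50.0, 5))
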