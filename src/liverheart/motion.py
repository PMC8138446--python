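"""Exhaustive-search block-matching optical flow for contraction videos.

Brightfield videos of spontaneously beating cardiac microtissues are
analysed by comparing the position of small macroblocks (8 x 8 px by
default) between frame ``i`` and frame ``i + lag`` (lag 5 at 100 Hz is
50 ms of motion).  For every block the integer displacement minimizing the
sum of absolute differences (SAD; SSD selectable) over the full search
window is reported - an exhaustive search, so the returned cost is the true
minimum by construction.  Ties are broken toward the smallest displacement
magnitude, then lexicographically, which makes the result deterministic.
The per-frame-pair mean speed series carries the contraction/relaxation
rhythm, from which the beat rate is extracted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

__all__ = [
    "VideoStack",
    "MotionField",
    "block_match",
    "motion_series",
    "beat_rate_from_motion",
    "load_video",
]


@dataclass
class VideoStack:
    """A grayscale video: frames indexed (t, y, x)."""

    frames: np.ndarray
    frame_rate: float  # Hz
    pixel_size_um: Optional[float] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (t, y, x) array")
        if self.frames.shape[0] < 6:
            raise ValueError("at least 6 frames are required")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    def __len__(self):
        return self.frames.shape[0]


def load_video(path, frame_rate: float, pixel_size_um: Optional[float] = None) -> VideoStack:
    """Read a multi-page TIFF stack."""
    import tifffile

    return VideoStack(tifffile.imread(path), frame_rate, pixel_size_um)


@dataclass
class MotionField:
    """Per-macroblock displacements between one frame pair."""

    dy: np.ndarray  # (nby, nbx) float; NaN for low-texture blocks
    dx: np.ndarray
    cost: np.ndarray  # matching cost at the reported displacement
    valid: np.ndarray  # bool mask (False = low-texture block skipped)
    block_size: int
    search_radius: int
    clamped: np.ndarray = None  # True where the best match sits on the window edge

    @property
    def speed(self) -> float:
        """Mean displacement magnitude (px/frame-pair) over valid blocks."""
        mag = np.hypot(self.dy, self.dx)[self.valid]
        return float(mag.mean()) if mag.size else 0.0


def _displacement_order(radius: int):
    """All integer displacements within the square window, sorted by
    magnitude then lexicographically - the tie-break priority."""
    disps = [(dy, dx) for dy in range(-radius, radius + 1)
             for dx in range(-radius, radius + 1)]
    disps.sort(key=lambda d: (d[0] * d[0] + d[1] * d[1], d))
    return disps


def _block_sums(img: np.ndarray, block: int, stride: int,
                ys: np.ndarray, xs: np.ndarray) -> np.ndarray:
    """Box sums of ``img`` over blocks anchored at (ys, xs) via an
    integral image."""
    ii = np.zeros((img.shape[0] + 1, img.shape[1] + 1))
    ii[1:, 1:] = img.cumsum(0).cumsum(1)
    return (
        ii[np.ix_(ys + block, xs + block)]
        - ii[np.ix_(ys + block, xs)]
        - ii[np.ix_(ys, xs + block)]
        + ii[np.ix_(ys, xs)]
    )


def block_match(
    frame_i: np.ndarray,
    frame_j: np.ndarray,
    *,
    block_size: int = 8,
    search_radius: int = 7,
    stride: Optional[int] = None,
    cost: str = "sad",
    var_threshold: float = 1e-12,
) -> MotionField:
    """Exhaustive-search block matching from ``frame_i`` to ``frame_j``.

    A block anchored at (y, x) in frame i is compared against the window of
    positions (y+dy, x+dx), |dy|,|dx| <= radius, in frame j; displacements
    whose target leaves the frame are excluded, so blocks near the border
    search a clipped window.  Blocks whose intensity variance falls below
    ``var_threshold`` carry no texture to match and report NaN.
    """
    a = np.asarray(frame_i, dtype=float)
    b = np.asarray(frame_j, dtype=float)
    if a.shape != b.shape:
        raise ValueError("frames must have the same shape")
    if block_size < 2:
        raise ValueError("block_size must be >= 2")
    if search_radius < 1:
        raise ValueError("search_radius must be >= 1")
    h, w = a.shape
    if h < block_size or w < block_size:
        raise ValueError("frame smaller than one block")
    stride = stride or block_size

    ys = np.arange(0, h - block_size + 1, stride)
    xs = np.arange(0, w - block_size + 1, stride)
    nby, nbx = ys.size, xs.size

    # texture check on frame i
    n_px = block_size * block_size
    s1 = _block_sums(a, block_size, stride, ys, xs)
    s2 = _block_sums(a * a, block_size, stride, ys, xs)
    var = s2 / n_px - (s1 / n_px) ** 2
    valid = var > var_threshold

    best_cost = np.full((nby, nbx), np.inf)
    best_dy = np.zeros((nby, nbx))
    best_dx = np.zeros((nby, nbx))

    for dy, dx in _displacement_order(search_radius):
        # overlap of the shifted grid with the frame
        oy = ys + dy
        ox = xs + dx
        in_y = (oy >= 0) & (oy <= h - block_size)
        in_x = (ox >= 0) & (ox <= w - block_size)
        if not (in_y.any() and in_x.any()):
            continue
        # difference image on the overlapping region of a and shifted b
        y0s, y0e = max(0, -dy), min(h, h - dy)
        x0s, x0e = max(0, -dx), min(w, w - dx)
        diff = a[y0s:y0e, x0s:x0e] - b[y0s + dy:y0e + dy, x0s + dx:x0e + dx]
        d = np.abs(diff) if cost == "sad" else diff * diff
        ii = np.zeros((d.shape[0] + 1, d.shape[1] + 1))
        ii[1:, 1:] = d.cumsum(0).cumsum(1)
        yy = ys[in_y] - y0s
        xx = xs[in_x] - x0s
        c = (
            ii[np.ix_(yy + block_size, xx + block_size)]
            - ii[np.ix_(yy + block_size, xx)]
            - ii[np.ix_(yy, xx + block_size)]
            + ii[np.ix_(yy, xx)]
        )
        sub = np.ix_(np.nonzero(in_y)[0], np.nonzero(in_x)[0])
        improved = c < best_cost[sub]
        bc = best_cost[sub]
        bdy = best_dy[sub]
        bdx = best_dx[sub]
        bc[improved] = c[improved]
        bdy[improved] = dy
        bdx[improved] = dx
        best_cost[sub] = bc
        best_dy[sub] = bdy
        best_dx[sub] = bdx

    clamped = (np.abs(best_dy) == search_radius) | (np.abs(best_dx) == search_radius)
    best_dy[~valid] = np.nan
    best_dx[~valid] = np.nan
    return MotionField(
        dy=best_dy, dx=best_dx, cost=best_cost, valid=valid,
        block_size=block_size, search_radius=search_radius, clamped=clamped,
    )


def motion_series(video: VideoStack, frame_lag: int = 5, **block_kwargs) -> np.ndarray:
    """Mean block speed for every frame pair (i, i + frame_lag), px/pair."""
    n = len(video)
    if frame_lag >= n:
        raise ValueError("frame_lag must be smaller than the video length")
    if frame_lag < 1:
        raise ValueError("frame_lag must be >= 1")
    out = np.empty(n - frame_lag)
    for i in range(n - frame_lag):
        out[i] = block_match(video.frames[i], video.frames[i + frame_lag], **block_kwargs).speed
    return out


def beat_rate_from_motion(
    series: np.ndarray,
    frame_rate: float,
    frame_lag: int = 5,
    *,
    peaks_per_beat: int = 2,
    prominence_frac: float = 0.5,
    smooth_s: float = 0.1,
) -> float:
    """Beat rate (BPM) from a motion-magnitude series.

    Each beat produces ``peaks_per_beat`` speed peaks (contraction and
    relaxation by default); the inter-beat interval is the median spacing
    between peaks one beat apart.  Returns NaN when too few peaks exist to
    define a full beat (fewer than ``peaks_per_beat + 1``).

    Because displacements are integer pixels, slow motion renders as a
    staircase whose individual steps would register as spurious peaks; the
    series is therefore smoothed over ``smooth_s`` seconds first.
    """
    s = np.asarray(series, dtype=float)
    rng = s.max() - s.min() if s.size else 0.0
    if rng <= 0:
        return float("nan")
    sigma = smooth_s * frame_rate
    if sigma >= 0.5:
        s = gaussian_filter1d(s, sigma)
        rng = s.max() - s.min()
        if rng <= 0:
            return float("nan")
    peaks, _ = find_peaks(s, prominence=prominence_frac * rng)
    if peaks.size < peaks_per_beat + 1:
        return float("nan")
    t = (peaks + frame_lag / 2.0) / frame_rate
    intervals = t[peaks_per_beat:] - t[:-peaks_per_beat]
    return 60.0 / float(np.median(intervals))
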