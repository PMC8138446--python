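"""Synthetic inputs with known ground truth for every analysis stage.

Wet-lab recordings (dye-based voltage traces, brightfield contraction
videos, dose-response tables, metabolite time courses) are emulated by
generators that return both the data in the exact format the analysis
modules consume and the per-item ground truth, so recovery can be tested
quantitatively.  Every generator is a pure function of its spec and seed:
re-running with the same arguments reproduces the output byte for byte.

The action-potential template deserves a note: the repolarizing flank is a
monotone cubic (PCHIP) drawn through the three specified crossing points
(30/80/90 % repolarization), so the configured APDs are exact properties
of the continuous waveform by construction, with no root finding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.ndimage import gaussian_filter

from .cardiac import VoltageTrace, fridericia, triangulation
from .hill import hill_response
from .metabolism import MetabolismParams, fraction_metabolized
from .motion import VideoStack

__all__ = [
    "APTemplateSpec",
    "VideoSpec",
    "make_ap_trace",
    "make_contraction_video",
    "make_dose_response",
    "make_metabolism_series",
]


@dataclass(frozen=True)
class APTemplateSpec:
    """Target shape of a synthetic optical action-potential train."""

    beat_rate_bpm: float = 30.0
    apd30_ms: float = 200.0
    apd80_ms: float = 400.0
    apd90_ms: float = 450.0
    amplitude: float = 1.0
    drift_per_s: float = 0.0  # linear baseline drift, a.u./s
    noise_sd: float = 0.0  # additive Gaussian noise, a.u.
    sampling_rate_hz: float = 500.0
    upstroke_ms: float = 10.0
    seed: int = 0

    @property
    def rr_s(self) -> float:
        return 60.0 / self.beat_rate_bpm

    def validate(self):
        if self.amplitude < 0 or self.noise_sd < 0:
            raise ValueError("amplitude and noise_sd must be non-negative")
        if not self.apd30_ms < self.apd80_ms < self.apd90_ms:
            raise ValueError("APD30 < APD80 < APD90 is required")
        if self.apd90_ms >= 0.85 * self.rr_s * 1e3:
            raise ValueError("APD90 must leave a diastolic interval before the next beat")
        if not self.apd30_ms > 3.0 * self.upstroke_ms:
            raise ValueError("APD30 too short for the upstroke duration")


def _ap_template(spec: APTemplateSpec):
    """Continuous single-beat waveform phi(tau), tau relative to activation.

    Half-cosine upstroke centred on tau=0 (so the maximum derivative - the
    activation reference - sits exactly at 0), a flat plateau, then a PCHIP
    flank pinned to (APD30, 0.7), (APD80, 0.2), (APD90, 0.1) of the
    amplitude, reaching the diastolic baseline shortly after APD90.
    """
    up = spec.upstroke_ms * 1e-3
    a30, a80, a90 = (x * 1e-3 for x in (spec.apd30_ms, spec.apd80_ms, spec.apd90_ms))
    plateau_end = max(up, 0.5 * a30)
    tail = a90 + min(0.1 * spec.rr_s, 0.1)
    knots = np.array([plateau_end, a30, a80, a90, tail])
    levels = np.array([1.0, 0.7, 0.2, 0.1, 0.0])
    flank = PchipInterpolator(knots, levels)

    def phi(tau):
        tau = np.asarray(tau, dtype=float)
        out = np.zeros_like(tau)
        rising = (tau >= -up / 2) & (tau < up / 2)
        out[rising] = 0.5 * (1.0 + np.sin(np.pi * tau[rising] / up))
        flat = (tau >= up / 2) & (tau < plateau_end)
        out[flat] = 1.0
        dec = (tau >= plateau_end) & (tau < tail)
        out[dec] = flank(tau[dec])
        return out

    return phi


def make_ap_trace(
    spec: APTemplateSpec, duration_s: float
) -> Tuple[VoltageTrace, pd.DataFrame]:
    """Generate a voltage trace plus its exact per-beat truth table."""
    spec.validate()
    rr = spec.rr_s
    first = 0.3 * rr
    n_beats = int(np.floor((duration_s - first - spec.apd90_ms * 1e-3 - 0.15) / rr)) + 1
    if n_beats < 3:
        raise ValueError("duration must cover at least 3 beats")
    phi = _ap_template(spec)
    t = np.arange(int(round(duration_s * spec.sampling_rate_hz))) / spec.sampling_rate_hz
    y = np.zeros_like(t)
    t_acts = first + rr * np.arange(n_beats)
    for ta in t_acts:
        y += spec.amplitude * phi(t - ta)
    y += spec.drift_per_s * t
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, size=y.shape)

    truth = pd.DataFrame(
        {
            "beat": np.arange(n_beats),
            "t_activation_s": t_acts,
            "apd30_ms": spec.apd30_ms,
            "apd80_ms": spec.apd80_ms,
            "apd90_ms": spec.apd90_ms,
            "rr_s": rr,
        }
    )
    for lv in (30, 80, 90):
        truth[f"capd{lv}_ms"] = fridericia(getattr(spec, f"apd{lv}_ms"), rr)
    truth["triangulation"] = triangulation(
        truth["capd30_ms"].iloc[0], truth["capd80_ms"].iloc[0]
    )
    trace = VoltageTrace(y, spec.sampling_rate_hz, meta={"synthetic": True, "seed": spec.seed})
    return trace, truth


@dataclass(frozen=True)
class VideoSpec:
    """Rigidly translated random texture emulating a contraction video."""

    shape: Tuple[int, int] = (64, 64)
    granularity_px: float = 2.0
    amplitude_px: float = 4.0
    period_s: float = 2.0
    frame_rate_hz: float = 50.0
    direction: Tuple[float, float] = (0.0, 1.0)  # (dy, dx) unit motion axis
    seed: int = 0

    def validate(self):
        if self.amplitude_px < 0:
            raise ValueError("amplitude_px must be non-negative")
        if self.period_s <= 2.0 / self.frame_rate_hz:
            raise ValueError("period must exceed two frame intervals")


def make_contraction_video(
    spec: VideoSpec, duration_s: float
) -> Tuple[VideoStack, pd.DataFrame]:
    """Beating-texture video plus the exact per-frame displacement truth.

    The displacement follows ``amp * sin^2(pi t / period)`` along the given
    axis - one excursion and return per beat, hence two speed peaks
    (contraction and relaxation) per cycle, half a period apart - and is
    rounded to whole pixels so block matching can recover it exactly.
    """
    spec.validate()
    h, w = spec.shape
    n = int(round(duration_s * spec.frame_rate_hz))
    if n < 6:
        raise ValueError("duration must give at least 6 frames")
    margin = int(np.ceil(spec.amplitude_px)) + 2
    rng = np.random.default_rng(spec.seed)
    canvas = gaussian_filter(rng.standard_normal((h + 2 * margin, w + 2 * margin)),
                             spec.granularity_px)
    canvas -= canvas.min()
    canvas /= max(canvas.max(), 1e-12)

    t = np.arange(n) / spec.frame_rate_hz
    d = spec.amplitude_px * np.sin(np.pi * t / spec.period_s) ** 2
    ey, ex = spec.direction
    norm = float(np.hypot(ey, ex)) or 1.0
    dy = np.rint(d * ey / norm).astype(int)
    dx = np.rint(d * ex / norm).astype(int)

    frames = np.empty((n, h, w))
    for k in range(n):
        oy, ox = margin - dy[k], margin - dx[k]
        frames[k] = canvas[oy:oy + h, ox:ox + w]
    truth = pd.DataFrame({"frame": np.arange(n), "t_s": t, "dy_px": dy, "dx_px": dx})
    video = VideoStack(frames, spec.frame_rate_hz, meta={"synthetic": True, "seed": spec.seed})
    return video, truth


def make_dose_response(
    ec50: float,
    *,
    slope: float = 1.0,
    floor: float = 1.0,
    ceiling: float = 1.35,
    doses: Sequence[float] = (1.0, 3.0, 10.0, 30.0, 100.0, 300.0),
    noise_cv: float = 0.0,
    n_reps: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Hill-shaped dose-response table with multiplicative Gaussian noise.

    Long format: one row per (dose, replicate) with the noisy response.
    """
    doses = np.asarray(doses, dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    mean = hill_response(doses, ec50, floor, ceiling, slope)
    for rep in range(n_reps):
        noisy = mean * (1.0 + rng.normal(0.0, noise_cv, size=doses.shape)) \
            if noise_cv > 0 else mean.copy()
        for d, r in zip(doses, noisy):
            rows.append({"dose_nm": d, "replicate": rep, "response": r})
    return pd.DataFrame(rows)


def make_metabolism_series(
    params: MetabolismParams,
    *,
    times_h: Sequence[float] = (3.0, 6.0, 24.0),
    inhibitor_levels_um: Sequence[float] = (0.0, 10.0),
    noise_sd_pct: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Metabolite-formation time courses (+/- inhibitor) from known kinetics."""
    rng = np.random.default_rng(seed)
    rows = []
    for i_um in inhibitor_levels_um:
        for t in times_h:
            f = fraction_metabolized(t, params, i_um)
            if noise_sd_pct > 0:
                f = max(f + rng.normal(0.0, noise_sd_pct), 0.0)
            rows.append({"time_h": t, "inhibitor_um": i_um, "fraction_pct": f})
    return pd.DataFrame(rows)
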