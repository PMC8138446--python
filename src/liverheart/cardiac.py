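"""Per-beat action-potential metrics from optical voltage traces.

Cardiac microtissues labelled with a voltage-sensitive dye report the
membrane potential as a fluorescence intensity time series.  This module
segments such a trace into beats and extracts, per beat, the action
potential duration at a chosen repolarization level (APDx: time from
activation to the first crossing of ``1 - x/100`` of the upstroke
amplitude on the repolarizing flank), the beat rate, the Fridericia
rate-corrected duration cAPDx = APDx / RR^(1/3) (RR in seconds, so a
60-BPM beat is the identity - the in vitro analogue of QTc), and the
triangulation metric (cAPD80 - cAPD30)/cAPD80, which grows as the
repolarization becomes more triangular and proarrhythmic.

Activation is referenced to the maximum upstroke derivative by default
(50 %-upstroke selectable); the diastolic baseline per beat is the median
of the last tenth of the preceding diastolic interval, which is robust to
slow drift; crossing times are sub-sample by linear interpolation so that
a 10-ms frame period does not quantize the APDs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d, percentile_filter
from scipy.signal import find_peaks

__all__ = [
    "VoltageTrace",
    "BeatDetectionConfig",
    "Beat",
    "segment_beats",
    "apd",
    "fridericia",
    "triangulation",
    "beat_metrics",
]


@dataclass
class VoltageTrace:
    """An optical voltage recording (arbitrary fluorescence units)."""

    samples: np.ndarray
    sampling_rate: float  # Hz
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.sampling_rate

    @classmethod
    def from_csv(cls, path, *, sampling_rate: Optional[float] = None,
                 time_col: str = "time_s", value_col: str = "fluorescence"):
        """Read a two-column delimited trace (time_s, fluorescence); if
        ``sampling_rate`` is given a single-column file is accepted."""
        df = pd.read_csv(path)
        if sampling_rate is not None and value_col not in df.columns:
            return cls(df.iloc[:, 0].to_numpy(), sampling_rate)
        t = df[time_col].to_numpy()
        fs = 1.0 / np.median(np.diff(t))
        return cls(df[value_col].to_numpy(), fs, t0=float(t[0]))


@dataclass
class BeatDetectionConfig:
    """Tunables for beat segmentation.

    ``baseline_window_s`` and ``baseline_percentile`` define the rolling-
    percentile detrend; ``min_prominence_frac`` is the peak prominence as a
    fraction of the detrended signal range; ``activation`` selects the
    activation reference.
    """

    baseline_window_s: float = 2.0
    baseline_percentile: float = 10.0
    min_prominence_frac: float = 0.4
    min_rr_s: float = 0.25
    smooth_ms: float = 0.0
    amplitude_floor: float = 1e-9
    activation: str = "max_derivative"  # or "upstroke50"


@dataclass
class Beat:
    """One segmented beat with its window and per-beat references."""

    t: np.ndarray  # window times, s
    y: np.ndarray  # detrended samples
    peak_index: int  # into the window
    activation_index: int
    activation_time: float  # s, sub-sample where applicable
    baseline: float
    amplitude: float


def _detrend(trace: VoltageTrace, cfg: BeatDetectionConfig) -> np.ndarray:
    win = max(3, int(round(cfg.baseline_window_s * trace.sampling_rate)) | 1)
    win = min(win, trace.samples.size)
    base = percentile_filter(trace.samples, cfg.baseline_percentile, size=win, mode="nearest")
    return trace.samples - base


def segment_beats(
    trace: VoltageTrace, config: Optional[BeatDetectionConfig] = None
) -> List[Beat]:
    """Split a trace into non-overlapping beat windows.

    Returns an empty list (with a warning) when no beats are detected;
    a flat trace is not an error.
    """
    cfg = config or BeatDetectionConfig()
    y = _detrend(trace, cfg)
    if cfg.smooth_ms > 0:
        y = gaussian_filter1d(y, cfg.smooth_ms * 1e-3 * trace.sampling_rate)
    rng = float(y.max() - y.min()) if y.size else 0.0
    if rng < cfg.amplitude_floor:
        warnings.warn("no beats detected (flat trace)", RuntimeWarning)
        return []
    peaks, _ = find_peaks(
        y,
        prominence=cfg.min_prominence_frac * rng,
        distance=max(1, int(cfg.min_rr_s * trace.sampling_rate)),
    )
    if peaks.size == 0:
        warnings.warn("no beats detected", RuntimeWarning)
        return []

    # window boundaries at the midpoint between successive peaks, so each
    # window contains the full repolarization and the following diastole
    bounds = [0]
    for a, b in zip(peaks[:-1], peaks[1:]):
        bounds.append(int((a + b) // 2))
    bounds.append(y.size)

    t = trace.times
    beats: List[Beat] = []
    for k, p in enumerate(peaks):
        lo, hi = bounds[k], bounds[k + 1]
        yw = y[lo:hi]
        tw = t[lo:hi]
        pk = p - lo
        up = yw[: pk + 1]
        if cfg.activation == "max_derivative":
            act = int(np.argmax(np.gradient(up))) if up.size > 1 else 0
        elif cfg.activation == "upstroke50":
            half = up[-1] / 2.0 if up.size else 0.0
            above = np.nonzero(up >= half)[0]
            act = int(above[0]) if above.size else 0
        else:
            raise ValueError(f"unknown activation mode {cfg.activation!r}")
        # diastolic baseline: median of the last 10 % of the pre-activation
        # interval (at least one sample)
        n_dia = max(1, act)
        n_tail = max(1, n_dia // 10)
        baseline = float(np.median(yw[act - n_tail:act] if act else yw[:1]))
        amplitude = float(yw[pk] - baseline)
        beats.append(
            Beat(
                t=tw,
                y=yw,
                peak_index=pk,
                activation_index=act,
                activation_time=float(tw[act]),
                baseline=baseline,
                amplitude=amplitude,
            )
        )
    return beats


def apd(beat: Beat, level: float) -> float:
    """Action potential duration (ms) at ``level`` percent repolarization.

    Measured from the activation time to the first crossing of
    ``baseline + amplitude*(1 - level/100)`` on the repolarizing flank,
    linearly interpolated between samples.  Returns NaN when the beat never
    repolarizes to that level inside its window (degenerate input).
    """
    if not 0.0 < level < 100.0:
        raise ValueError("repolarization level must lie in (0, 100)")
    if beat.amplitude <= 0:
        return float("nan")
    threshold = beat.baseline + beat.amplitude * (1.0 - level / 100.0)
    y = beat.y
    t = beat.t
    below = np.nonzero(y[beat.peak_index:] <= threshold)[0]
    if below.size == 0:
        return float("nan")
    i = beat.peak_index + below[0]
    if i == beat.peak_index:
        t_cross = t[i]
    else:
        y0, y1 = y[i - 1], y[i]
        frac = (threshold - y0) / (y1 - y0) if y1 != y0 else 1.0
        t_cross = t[i - 1] + frac * (t[i] - t[i - 1])
    return (t_cross - beat.activation_time) * 1e3


def fridericia(apd_ms: float, rr_s: float) -> float:
    """Fridericia cube-root rate correction, cAPD = APD / RR^(1/3).

    With RR in seconds a 60-BPM rhythm (RR = 1 s) is the identity, matching
    the clinical QTc convention this is borrowed from.
    """
    if not rr_s > 0:
        raise ValueError("RR interval must be positive")
    return apd_ms / rr_s ** (1.0 / 3.0)


def triangulation(capd30: float, capd80: float) -> float:
    """(cAPD80 - cAPD30) / cAPD80; 0 is a rectangular action potential.

    A value reported from capd30 > capd80 would mean the faster
    repolarization level crossed later - a segmentation failure - and is
    rejected.
    """
    if not capd80 > 0:
        raise ValueError("cAPD80 must be positive")
    if capd30 > capd80:
        raise ValueError("cAPD30 > cAPD80 indicates a segmentation failure")
    return (capd80 - capd30) / capd80


def beat_metrics(
    trace: VoltageTrace,
    config: Optional[BeatDetectionConfig] = None,
    levels: Sequence[float] = (30.0, 80.0, 90.0),
) -> pd.DataFrame:
    """Tidy per-beat metrics table.

    One row per detected beat with activation time, APD at each requested
    level (ms), the RR interval (s; the first beat borrows the following
    interval), beat rate (BPM), Fridericia-corrected durations and the
    triangulation metric when both 30 and 80 are among the levels.
    """
    beats = segment_beats(trace, config)
    rows = []
    t_act = np.array([b.activation_time for b in beats])
    rr = np.full(len(beats), np.nan)
    if len(beats) >= 2:
        d = np.diff(t_act)
        rr[1:] = d
        rr[0] = d[0]
    for k, b in enumerate(beats):
        row = {"beat": k, "t_activation_s": b.activation_time, "rr_s": rr[k]}
        row["beat_rate_bpm"] = 60.0 / rr[k] if rr[k] > 0 else np.nan
        for lv in levels:
            row[f"apd{int(lv)}_ms"] = apd(b, lv)
        for lv in levels:
            a = row[f"apd{int(lv)}_ms"]
            row[f"capd{int(lv)}_ms"] = (
                fridericia(a, rr[k]) if np.isfinite(a) and rr[k] > 0 else np.nan
            )
        if 30.0 in levels and 80.0 in levels:
            c30, c80 = row.get("capd30_ms"), row.get("capd80_ms")
            row["triangulation"] = (
                triangulation(c30, c80)
                if np.isfinite(c30) and np.isfinite(c80) and 0 < c30 <= c80
                else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)
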