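"""Gait parameters from the vertical (up–down) motion acceleration.

Each straight walk covers the full lane (20 m by default), so stride
length is lane length divided by the step count, cadence is the dominant
spectral frequency of the vertical motion, gait velocity their product,
and total distance ``lane·p + SL·q`` with ``p`` complete lanes and ``q``
steps in the final partial lane.  An ankle sensor registers both feet's
impacts on the vertical axis, so the cadence is at step (not stride)
frequency, about 2 step/s for healthy elderly walkers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import fft as sp_fft
from scipy import signal

from .preprocess import design_lowpass, separate_gravity, smooth_motion
from .segmentation import count_complete_sw, detect_segments
from .types import (
    AccelTrace,
    AnalysisConfig,
    GaitSummary,
    SegmentLabel,
    SegmentParams,
    WalkSegment,
)

logger = logging.getLogger(__name__)


@dataclass
class StepEvents:
    """Detected step impacts within one straight-walk segment."""

    segment_ref: Optional[WalkSegment]
    peak_times: np.ndarray  # s, strictly increasing, inside the segment

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        if self.peak_times.size and np.any(np.diff(self.peak_times) <= 0):
            raise ValueError("peak_times must be strictly increasing")

    @property
    def n_steps(self) -> int:
        return len(self.peak_times)


def step_cadence(
    y_motion: np.ndarray, fs: float, config: Optional[AnalysisConfig] = None
) -> float:
    """Dominant frequency [step/s] of the vertical motion in the cadence band.

    The segment is mean-removed, Hann-tapered and zero-padded so the
    spectral grid is no coarser than ``config.freq_resolution`` (0.02 Hz);
    the cadence is the frequency of the largest magnitude bin within the
    cadence band.
    """
    config = config or AnalysisConfig()
    y = np.asarray(y_motion, dtype=float)
    if len(y) < 3 * fs:
        raise ValueError(f"segment shorter than 3 s ({len(y) / fs:.2f} s)")
    if not np.any(y != 0):
        raise ValueError("all-zero segment has no cadence")
    y = y - y.mean()
    y = y * np.hanning(len(y))
    n = sp_fft.next_fast_len(max(len(y), int(np.ceil(fs / config.freq_resolution))))
    spec = np.abs(sp_fft.rfft(y, n))
    freqs = sp_fft.rfftfreq(n, 1.0 / fs)
    lo, hi = config.cadence_band
    band = (freqs >= lo) & (freqs <= hi)
    if not band.any() or not np.any(spec[band] > 0):
        raise ValueError("no spectral energy inside the cadence band")
    return float(freqs[band][np.argmax(spec[band])])


def count_steps(
    y_motion: np.ndarray,
    fs: float,
    sc_seed: float,
    config: Optional[AnalysisConfig] = None,
    t0: float = 0.0,
    segment: Optional[WalkSegment] = None,
    min_duration: float = 3.0,
) -> StepEvents:
    """Detect step impacts as peaks of the cadence-band vertical motion.

    The signal is band-passed around the spectral cadence seed
    (``[0.55, 1.6]·sc_seed`` clipped to the cadence band), which isolates
    the step fundamental; peaks then need spacing ≥ 0.5/sc_seed and
    prominence ≥ 1·MAD of the filtered segment.
    """
    config = config or AnalysisConfig()
    y = np.asarray(y_motion, dtype=float)
    if len(y) < min_duration * fs:
        raise ValueError(f"segment shorter than {min_duration} s ({len(y) / fs:.2f} s)")
    if sc_seed <= 0:
        raise ValueError("sc_seed must be positive")
    lo = max(0.55 * sc_seed, config.cadence_band[0])
    hi = min(1.6 * sc_seed, config.cadence_band[1] * 1.6)
    hi = min(hi, 0.49 * fs)
    sos = signal.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
    yf = signal.sosfiltfilt(sos, y)
    mad = float(np.median(np.abs(yf - np.median(yf))))
    if mad <= 0:
        return StepEvents(segment_ref=segment, peak_times=np.array([]))
    distance = max(1, int(round(0.5 / sc_seed * fs)))
    peaks, _ = signal.find_peaks(yf, distance=distance, prominence=mad)
    return StepEvents(segment_ref=segment, peak_times=t0 + peaks / fs)


def stride_length(n_steps: int, lane_length: float) -> float:
    """Stride length [m/step] over a fully traversed lane: lane / step count."""
    if n_steps < 1:
        raise ValueError("a complete straight walk must contain at least one step")
    return lane_length / n_steps


def gait_velocity(sl: float, sc: float) -> float:
    """Gait velocity [m/s] = stride length × cadence (per-test SW means)."""
    if sl < 0 or sc < 0:
        raise ValueError("sl and sc must be non-negative")
    return sl * sc


def six_mwd(p: int, sl_mean: float, q: int, lane_length: float) -> float:
    """Six-minute walking distance [m]: lane·p complete lanes + SL·q partial steps."""
    if p < 0 or q < 0:
        raise ValueError("p and q must be non-negative")
    return lane_length * p + sl_mean * q


def analyze_trace(
    trace: AccelTrace, config: Optional[AnalysisConfig] = None
) -> tuple[GaitSummary, list[WalkSegment]]:
    """Run the full single-trace pipeline: preprocess → segment → gait parameters.

    Returns the gait summary (six_mwee unset — it needs subject
    anthropometrics) and the detected segments.  Invalid complete SW
    segments (no detectable steps) still count toward ``p`` — the lane was
    traversed — but are excluded from the SL/SC means.
    """
    config = config or AnalysisConfig()
    coeffs = design_lowpass(config.fc, trace.fs)
    _, motion = separate_gravity(trace, coeffs)
    # drop the filter warm-up at the start of the recording
    motion = motion.slice_time(motion.t[0] + config.warmup, np.inf)
    if config.use_kalman:
        motion = smooth_motion(motion, q=config.kalman_q, r=config.kalman_r)
    # the turn detector gets the raw (cropped) trace: it removes its own
    # slow baseline, which preserves the ~0.25 Hz turn swing that the
    # causal 0.2 Hz gravity filter would partly absorb and smear
    segments = detect_segments(
        trace.slice_time(trace.t[0] + config.warmup, np.inf), config
    )
    p, final_partial = count_complete_sw(segments)

    per_segment: list[SegmentParams] = []
    sls: list[float] = []
    scs: list[float] = []
    sw_index = 0
    for seg in segments:
        if seg.label != SegmentLabel.SW or not seg.complete:
            continue
        y = motion.slice_time(seg.start, seg.end).y
        try:
            sc_i = step_cadence(y, motion.fs, config)
            events = count_steps(y, motion.fs, sc_i, config, t0=seg.start, segment=seg)
        except ValueError as exc:
            logger.warning("segment %d flagged invalid: %s", sw_index, exc)
            per_segment.append(SegmentParams(sw_index, 0, None, None, True, valid=False))
            sw_index += 1
            continue
        if events.n_steps == 0:
            logger.warning("segment %d has no detectable steps; excluded from means", sw_index)
            per_segment.append(SegmentParams(sw_index, 0, None, None, True, valid=False))
            sw_index += 1
            continue
        sl_i = stride_length(events.n_steps, config.lane_length)
        per_segment.append(SegmentParams(sw_index, events.n_steps, sl_i, sc_i, True))
        sls.append(sl_i)
        scs.append(sc_i)
        sw_index += 1

    if not sls:
        raise ValueError("no valid complete straight-walk segments in trace")
    sl = float(np.mean(sls))
    sc = float(np.mean(scs))

    q = 0
    if final_partial is not None:
        y = motion.slice_time(final_partial.start, final_partial.end).y
        if len(y) >= 0.5 * motion.fs:  # ignore partial lanes shorter than 0.5 s
            try:
                events = count_steps(
                    y, motion.fs, sc, config, t0=final_partial.start,
                    segment=final_partial, min_duration=0.5,
                )
                q = events.n_steps
            except ValueError:
                q = 0
        per_segment.append(
            SegmentParams(sw_index, q, None, None, complete=False)
        )

    summary = GaitSummary(
        sl=sl,
        sc=sc,
        gv=gait_velocity(sl, sc),
        six_mwd=six_mwd(p, sl, q, config.lane_length),
        n_complete_sw=p,
        final_partial_steps=q,
        lane_length=config.lane_length,
        per_segment=per_segment,
    )
    return summary, segments
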