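"""Split a 6MWT trace into straight-walk (SW) and U-turn-walk (UW) segments.

During a U-turn the mediolateral (x) axis swings far more than during
straight walking, so U-turns appear as bursts of x-axis energy.  The
detector removes a slow baseline from x with a long moving average (so it
works equally on raw or gravity-separated input, and the ~0.25 Hz turn
swing is not attenuated the way a 0.2 Hz gravity filter would), takes a
moving RMS, thresholds it at median + 2·MAD, and refines each burst's
boundaries to where the RMS crosses a fraction of the burst's peak above
the base threshold (a plain threshold inflates each burst by half the RMS
window).  Straight walks are the complement; the segments tile the trace
with alternating labels.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import median_filter

from .types import AccelTrace, AnalysisConfig, SegmentLabel, WalkSegment, validate_segments

logger = logging.getLogger(__name__)


def moving_rms(x: np.ndarray, fs: float, window: float) -> np.ndarray:
    """Centered moving RMS with the given window [s] (same length as input).

    Near the edges the mean is taken over the samples actually covered, so
    a burst touching the end of the trace is not underestimated.
    """
    w = max(1, int(round(window * fs)))
    kernel = np.ones(w)
    power = np.convolve(np.asarray(x, dtype=float) ** 2, kernel, mode="same")
    coverage = np.convolve(np.ones_like(power), kernel, mode="same")
    return np.sqrt(np.maximum(power / coverage, 0.0))


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index runs where mask is True."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[::2], idx[1::2]))


def detect_segments(
    motion: AccelTrace, config: Optional[AnalysisConfig] = None
) -> list[WalkSegment]:
    """Detect alternating SW/UW segments from the x-axis motion signal.

    Returns segments tiling ``[t[0], t[-1] + 1/fs)``; the trailing SW (not
    followed by a turn) is marked ``complete=False``.  A trace with no
    x-axis activity yields a single SW segment.
    """
    config = config or AnalysisConfig()
    if motion.duration < 5.0:
        raise ValueError(f"need at least 5 s of motion, got {motion.duration:.2f} s")
    t0 = float(motion.t[0])
    t_end = float(motion.t[-1]) + 1.0 / motion.fs

    # moving-median baseline: unlike a moving mean it does not smear a
    # 2 s turn burst across the whole window; edges are clamped to the
    # nearest fully-covered window so padding cannot skew the median
    w = max(1, int(round(config.baseline_window * motion.fs)))
    baseline = median_filter(np.asarray(motion.x, dtype=float), size=w, mode="nearest")
    half = w // 2
    if len(baseline) > w:
        baseline[:half] = baseline[half]
        baseline[-half:] = baseline[-half - 1]
    x_det = motion.x - baseline
    rms = moving_rms(x_det, motion.fs, config.rms_window)
    med = float(np.median(rms))
    mad = float(np.median(np.abs(rms - med)))
    thr = med + 2.0 * mad

    if float(np.var(motion.x)) < 1e-24:
        logger.warning("x axis has zero variance; returning a single SW segment")
        return [WalkSegment(SegmentLabel.SW, t0, t_end, complete=False)]

    mask = rms > thr
    uw_runs: list[tuple[int, int]] = []
    for i0, i1 in _runs(mask):
        peak = float(rms[i0:i1].max())
        # a genuine turn towers over the straight-walk RMS floor; runs whose
        # peak is within noise-maximum reach of the floor are excursions
        if peak < med + config.uw_peak_mads * mad:
            continue
        # refine boundaries: keep the contiguous core around the peak that
        # stays above thr + frac*(peak-thr); expanding from the peak (rather
        # than taking first/last crossing) ignores isolated spikes in the run
        # floor at a fixed fraction of the peak so the level stays above
        # window-smear skirts even when the noise floor (and thr) is ~0
        level = max(thr + config.uw_refine_frac * (peak - thr),
                    config.uw_level_floor * peak)
        kp = i0 + int(np.argmax(rms[i0:i1]))
        j0 = kp
        while j0 > i0 and rms[j0 - 1] >= level:
            j0 -= 1
        j1 = kp + 1
        while j1 < i1 and rms[j1] >= level:
            j1 += 1
        if (j1 - j0) / motion.fs >= config.uw_min_duration:
            uw_runs.append((j0, j1))

    # merge turns separated by an implausibly short straight walk
    merged: list[tuple[int, int]] = []
    for run in uw_runs:
        if merged and (run[0] - merged[-1][1]) / motion.fs < config.sw_min_duration:
            merged[-1] = (merged[-1][0], run[1])
        else:
            merged.append(run)
    uw_runs = merged

    if not uw_runs:
        return [WalkSegment(SegmentLabel.SW, t0, t_end, complete=False)]

    segments: list[WalkSegment] = []
    cursor = t0
    for j0, j1 in uw_runs:
        uw_start = float(motion.t[j0])
        uw_end = float(motion.t[j1 - 1]) + 1.0 / motion.fs if j1 < len(motion.t) + 1 else t_end
        uw_end = min(uw_end, t_end)
        if uw_start > cursor:
            segments.append(WalkSegment(SegmentLabel.SW, cursor, uw_start, complete=True))
        elif segments and segments[-1].label == SegmentLabel.UW:
            # turn starting exactly at the cursor after another turn: extend
            segments[-1] = WalkSegment(SegmentLabel.UW, segments[-1].start, uw_end)
            cursor = uw_end
            continue
        segments.append(WalkSegment(SegmentLabel.UW, uw_start, uw_end))
        cursor = uw_end
    if cursor < t_end:
        segments.append(WalkSegment(SegmentLabel.SW, cursor, t_end, complete=False))

    validate_segments(segments)
    return segments


def count_complete_sw(
    segments: Sequence[WalkSegment],
) -> tuple[int, Optional[WalkSegment]]:
    """Number of complete straight walks p, and the trailing partial SW if any.

    An SW is complete when a UW follows it (the subject reached the lane
    end and turned); a trailing SW with no following turn is the final
    partial lane.
    """
    p = 0
    final_partial: Optional[WalkSegment] = None
    for i, seg in enumerate(segments):
        if seg.label != SegmentLabel.SW:
            continue
        followed_by_uw = any(s.label == SegmentLabel.UW for s in segments[i + 1:])
        if followed_by_uw:
            p += 1
        else:
            final_partial = seg
    return p, final_partial
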