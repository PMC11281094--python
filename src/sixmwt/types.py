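"""Core domain types for six-minute-walk-test (6MWT) gait analysis.

The axis convention is fixed by how the sensor is worn behind the ankle:
``x`` is the left–right (mediolateral) axis, ``y`` the up–down (vertical)
axis, and ``z`` the walking (anteroposterior) axis.  Accelerations are
stored in m/s²; times in seconds from test start; sample indexing is
0-based and all intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum, IntEnum
from typing import Optional, Sequence

import numpy as np

#: standard gravity, used to convert traces recorded in g to m/s²
G_STANDARD = 9.80665

AXIS_CONVENTION = {"x": "left-right", "y": "up-down", "z": "walking direction"}


class Gender(IntEnum):
    """Gender coding used by the metabolic and frailty formulas (1: male, 2: female)."""

    MALE = 1
    FEMALE = 2


class SegmentLabel(str, Enum):
    SW = "SW"  # straight walk along the lane
    UW = "UW"  # U-turn walk at the lane end


@dataclass
class AccelTrace:
    """A tri-axial acceleration time series from one ankle-worn sensor.

    Parameters
    ----------
    t, x, y, z
        Equal-length arrays: sample times [s] and per-axis acceleration
        [m/s²].  ``t`` must be strictly increasing with spacing 1/fs
        within 1%.
    fs
        Sampling rate [Hz] (50 Hz for the wearable used here).
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    fs: float
    sensor_id: str = "sensor"
    unit: str = "m/s2"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        n = len(self.t)
        for name in ("x", "y", "z"):
            if len(getattr(self, name)) != n:
                raise ValueError(
                    f"axis {name!r} has {len(getattr(self, name))} samples, "
                    f"expected {n} to match t"
                )
        if n >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                row = int(np.argmax(dt <= 0)) + 1
                raise ValueError(f"time not strictly increasing at row {row}")
            nominal = 1.0 / self.fs
            if np.any(np.abs(dt - nominal) > 0.01 * nominal):
                row = int(np.argmax(np.abs(dt - nominal) > 0.01 * nominal)) + 1
                raise ValueError(
                    f"sample spacing at row {row} deviates more than 1% "
                    f"from 1/fs={nominal:.6g} s"
                )

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        """Span covered by the samples, [s]."""
        return len(self) / self.fs

    def slice_time(self, start: float, end: float) -> "AccelTrace":
        """Return the sub-trace with t in the half-open window [start, end)."""
        mask = (self.t >= start) & (self.t < end)
        return AccelTrace(
            t=self.t[mask], x=self.x[mask], y=self.y[mask], z=self.z[mask],
            fs=self.fs, sensor_id=self.sensor_id, unit=self.unit,
        )


@dataclass
class SubjectRecord:
    """Demographics and clinical items for one participant.

    ``handgrip`` [kg] and ``speed5m`` [m/s, five-meter walking test] are the
    two clinical frailty items; the three ``q_*`` booleans are the
    questionnaire items (weight loss, exhaustion, low physical activity).
    Any field may be None when not collected; operations that need a field
    raise with its name.
    """

    subject_id: str
    age: Optional[float] = None
    gender: Optional[Gender] = None
    weight: Optional[float] = None   # kg
    height: Optional[float] = None   # cm
    handgrip: Optional[float] = None  # kg
    speed5m: Optional[float] = None   # m/s
    q_weight_loss: Optional[bool] = None
    q_exhaustion: Optional[bool] = None
    q_low_activity: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.gender is not None:
            self.gender = Gender(self.gender)  # raises on anything but 1/2
        for name in ("age", "weight", "height", "handgrip", "speed5m"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be > 0, got {v}")


@dataclass
class AnalysisConfig:
    """Tunable parameters of the analysis pipeline (all config-exposed).

    Defaults follow the study protocol: a 20 m straight lane, 0.2 Hz
    gravity-filter cutoff at fs=50 Hz, a 0.5–4 Hz cadence search band,
    SL/SC frailty-map cutoffs of 0.6 m/step and 2.0 step/s, a 400 m
    walking-distance threshold and a 360 s test.
    """

    lane_length: float = 20.0        # m
    fc: float = 0.2                  # Hz, gravity low-pass cutoff
    cadence_band: tuple[float, float] = (0.5, 4.0)  # Hz
    cut_sl: float = 0.6              # m/step
    cut_sc: float = 2.0              # step/s
    sixmwd_threshold: float = 400.0  # m
    test_duration: float = 360.0     # s
    # detector parameters (turn segmentation)
    rms_window: float = 1.0          # s, moving-RMS window on the x axis
    baseline_window: float = 8.0     # s, slow-baseline removal before the RMS
    uw_min_duration: float = 0.8     # s
    sw_min_duration: float = 3.0     # s
    uw_refine_frac: float = 0.15     # boundary refinement level within a run
    uw_peak_mads: float = 8.0        # min run peak above the RMS floor, in MADs
    uw_level_floor: float = 0.3      # refinement level floor, fraction of run peak
    # preprocessing
    warmup: float = 1.0              # s excluded from analysis (filter transient)
    use_kalman: bool = True
    kalman_q: float = 1e-2           # process-noise intensity, (m/s²)²
    kalman_r: Optional[float] = None  # None -> var(diff(signal))/2
    # spectral cadence estimation
    freq_resolution: float = 0.02    # Hz, max spacing of the padded spectrum

    def __post_init__(self) -> None:
        for name in (
            "lane_length", "fc", "cut_sl", "cut_sc", "sixmwd_threshold",
            "test_duration", "rms_window", "baseline_window", "uw_min_duration",
            "sw_min_duration", "warmup", "kalman_q", "freq_resolution",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.cadence_band
        if not (0 < lo < hi):
            raise ValueError(f"cadence_band must satisfy 0 < lower < upper, got {self.cadence_band}")
        if self.kalman_r is not None and not self.kalman_r > 0:
            raise ValueError("kalman_r must be positive when given")


@dataclass
class WalkSegment:
    """One labeled interval of the test: straight walk (SW) or U-turn (UW)."""

    label: SegmentLabel
    start: float  # s
    end: float    # s
    complete: bool = True  # for SW: traversed the full lane (followed by a UW)

    def __post_init__(self) -> None:
        self.label = SegmentLabel(self.label)
        if not self.start < self.end:
            raise ValueError(f"segment start {self.start} must be < end {self.end}")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class SegmentParams:
    """Per-straight-walk gait parameters (one row of the per-segment table)."""

    index: int
    n_steps: int
    sl: Optional[float]  # m/step; None when the segment was flagged invalid
    sc: Optional[float]  # step/s
    complete: bool
    valid: bool = True


@dataclass
class GaitSummary:
    """Gait parameters for one 6MWT.

    ``sl`` and ``sc`` are means over the complete straight-walk segments,
    ``gv = sl*sc``, and ``six_mwd = lane_length*p + sl*q`` where ``p`` is
    the number of complete straight walks and ``q`` the step count of the
    final partial lane.  ``six_mwee`` [kcal/h] is attached once subject
    anthropometrics are available, else None.
    """

    sl: float
    sc: float
    gv: float
    six_mwd: float
    n_complete_sw: int
    final_partial_steps: int
    lane_length: float
    six_mwee: Optional[float] = None
    per_segment: list[SegmentParams] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sl < 0 or self.sc < 0 or self.gv < 0:
            raise ValueError("sl, sc, gv must be non-negative")
        if not math.isclose(self.gv, self.sl * self.sc, rel_tol=1e-9, abs_tol=1e-12):
            raise ValueError(
                f"gv={self.gv} inconsistent with sl*sc={self.sl * self.sc}"
            )
        expected = self.lane_length * self.n_complete_sw + self.sl * self.final_partial_steps
        if not math.isclose(self.six_mwd, expected, rel_tol=1e-9, abs_tol=1e-9):
            raise ValueError(
                f"six_mwd={self.six_mwd} inconsistent with "
                f"lane*p + sl*q = {expected}"
            )


def validate_segments(segments: Sequence[WalkSegment], *, atol: float = 1e-6) -> None:
    """Assert the segment-tiling invariant: contiguous, non-overlapping, alternating labels."""
    for a, b in zip(segments, segments[1:]):
        if abs(a.end - b.start) > atol:
            raise ValueError(f"segments do not tile: gap between {a.end} and {b.start}")
        if a.label == b.label:
            raise ValueError(f"labels do not alternate at t={b.start}")
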