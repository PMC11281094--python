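"""Synthetic 6MWT accelerometer traces and cohorts with known ground truth.

The trace generator emulates the measurement model the pipeline expects:
a constant gravity component, a vertical raised-cosine (or Gaussian)
impulse per step at a controlled cadence, a small forward oscillation,
low-frequency mediolateral swings during U-turns (with cadence reduced
20%), and additive white sensor noise.  A 1 s standing lead-in precedes
walking, matching the pipeline's filter warm-up crop.  The cohort
generator draws gait parameters from per-group distributions whose
defaults are the published frail / pre-frail / non-frail cohort means and
SDs, with frailty items drawn consistently with each group label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .types import G_STANDARD, AccelTrace, SegmentLabel, WalkSegment
from .frailty import FRAIL, NON_FRAIL, PRE_FRAIL


@dataclass
class WalkScenario:
    """Parameters of one simulated 6MWT."""

    cadence: float = 2.0        # step/s
    stride: float = 0.6         # m/step
    lane_length: float = 20.0   # m
    test_duration: float = 360.0  # s
    turn_duration: float = 2.0  # s
    lead_in: float = 1.0        # s standing before the start signal
    noise_sd: float = 0.3       # m/s² white noise per axis
    step_pulse_shape: str = "raised-cosine"  # or "gaussian"
    pulse_width: float = 0.15   # s
    pulse_amp: float = 3.0      # m/s²
    forward_amp: float = 0.5    # m/s², z-axis sway at half cadence
    turn_swing_amp: Optional[float] = None  # None -> max(1.5, 3·noise_sd)
    turn_cadence_factor: float = 0.8
    gravity_orientation: tuple[float, float, float] = (0.0, 1.0, 0.0)
    fs: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.5 <= self.cadence <= 4.0:
            raise ValueError(f"cadence must lie in [0.5, 4], got {self.cadence}")
        for name in ("stride", "lane_length", "test_duration", "turn_duration",
                     "pulse_width", "pulse_amp", "fs"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.lead_in < 0 or self.noise_sd < 0:
            raise ValueError("lead_in and noise_sd must be non-negative")
        if self.step_pulse_shape not in ("raised-cosine", "gaussian"):
            raise ValueError(f"unknown pulse shape {self.step_pulse_shape!r}")
        g = np.asarray(self.gravity_orientation, dtype=float)
        if not np.isclose(np.linalg.norm(g), 1.0, atol=1e-9):
            raise ValueError("gravity_orientation must be a unit vector")

    @property
    def steps_per_lane(self) -> int:
        return int(round(self.lane_length / self.stride))

    @property
    def swing_amp(self) -> float:
        if self.turn_swing_amp is not None:
            return self.turn_swing_amp
        return max(1.5, 3.0 * self.noise_sd)


@dataclass
class GroundTruth:
    """What the generator actually produced, for recovery tests."""

    step_times: np.ndarray          # s, lane steps only (not turn steps)
    segments: list[WalkSegment]
    steps_per_lane: int
    true_sl: float
    true_sc: float
    true_gv: float
    true_six_mwd: float
    p: int                          # complete lanes
    q: int                          # steps in the final partial lane
    turn_step_times: np.ndarray = field(default_factory=lambda: np.array([]))


def _pulse(t: np.ndarray, center: float, width: float, amp: float, shape: str) -> np.ndarray:
    if shape == "raised-cosine":
        out = np.zeros_like(t)
        m = np.abs(t - center) <= width / 2
        out[m] = amp * 0.5 * (1.0 + np.cos(2 * np.pi * (t[m] - center) / width))
        return out
    sigma = width / 4.0  # ±2σ support comparable to the raised-cosine width
    return amp * np.exp(-0.5 * ((t - center) / sigma) ** 2)


def simulate_6mwt(scenario: WalkScenario) -> tuple[AccelTrace, GroundTruth]:
    """Generate one synthetic 6MWT trace plus its ground truth.

    The walk alternates full lanes (``steps_per_lane`` steps at the set
    cadence) and U-turns until the test clock runs out; a lane cut off by
    the clock becomes the final partial straight walk.  Fixed seed ⇒
    byte-identical output.
    """
    fs = scenario.fs
    duration = scenario.test_duration
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    step_times: list[float] = []
    turn_step_times: list[float] = []
    segments: list[WalkSegment] = []
    k = scenario.steps_per_lane
    step_dt = 1.0 / scenario.cadence
    turn_dt = 1.0 / (scenario.turn_cadence_factor * scenario.cadence)

    cursor = scenario.lead_in
    sw_start = 0.0
    p = 0
    q = 0
    while True:
        lane_end = cursor + k * step_dt
        if lane_end >= duration:
            # partial lane until the clock stops
            times = [cursor + (i + 0.5) * step_dt for i in range(k)]
            times = [s for s in times if s < duration - scenario.pulse_width / 2]
            step_times.extend(times)
            q = len(times)
            if sw_start < duration:
                segments.append(WalkSegment(SegmentLabel.SW, sw_start, duration, complete=False))
            break
        step_times.extend(cursor + (i + 0.5) * step_dt for i in range(k))
        p += 1
        segments.append(WalkSegment(SegmentLabel.SW, sw_start, lane_end, complete=True))
        turn_end = lane_end + scenario.turn_duration
        seg_turn_end = min(turn_end, duration)
        segments.append(WalkSegment(SegmentLabel.UW, lane_end, seg_turn_end))
        # shuffle steps through the pivot, with a half-step deceleration
        # margin before straight walking resumes
        j = 0
        while lane_end + (j + 0.5) * turn_dt < seg_turn_end - 0.5 * turn_dt:
            turn_step_times.append(lane_end + (j + 0.5) * turn_dt)
            j += 1
        if turn_end >= duration:
            break
        cursor = turn_end
        sw_start = turn_end

    # vertical motion: one impulse per step (lane and turn steps alike)
    y_motion = np.zeros(n)
    for s in step_times:
        y_motion += _pulse(t, s, scenario.pulse_width, scenario.pulse_amp,
                           scenario.step_pulse_shape)
    for s in turn_step_times:
        y_motion += _pulse(t, s, scenario.pulse_width,
                           0.8 * scenario.pulse_amp, scenario.step_pulse_shape)

    # forward sway at half the step rate, only while walking
    z_motion = scenario.forward_amp * np.sin(np.pi * scenario.cadence * t)
    z_motion[t < scenario.lead_in] = 0.0

    # mediolateral half-sine swing during each U-turn
    x_motion = np.zeros(n)
    for seg in segments:
        if seg.label != SegmentLabel.UW:
            continue
        m = (t >= seg.start) & (t < seg.end)
        x_motion[m] += scenario.swing_amp * np.sin(
            np.pi * (t[m] - seg.start) / seg.duration
        )

    rng = np.random.default_rng(scenario.seed)
    gx, gy, gz = np.asarray(scenario.gravity_orientation) * G_STANDARD
    noise = rng.normal(0.0, scenario.noise_sd, size=(3, n)) if scenario.noise_sd > 0 \
        else np.zeros((3, n))

    trace = AccelTrace(
        t=t,
        x=gx + x_motion + noise[0],
        y=gy + y_motion + noise[1],
        z=gz + z_motion + noise[2],
        fs=fs,
        sensor_id=f"sim-{scenario.seed}",
    )
    true_sl = scenario.lane_length / k
    truth = GroundTruth(
        step_times=np.asarray(step_times),
        segments=segments,
        steps_per_lane=k,
        true_sl=true_sl,
        true_sc=scenario.cadence,
        true_gv=true_sl * scenario.cadence,
        true_six_mwd=scenario.lane_length * p + true_sl * q,
        p=p,
        q=q,
        turn_step_times=np.asarray(turn_step_times),
    )
    return trace, truth


#: Published cohort distributions (mean, SD) per group: SL [m/step],
#: SC [step/s], 6MWEE [kcal/h], 6MWD [m], plus each group's share of the
#: 60-subject cohort.
DEFAULT_GROUP_SPECS: dict[str, dict] = {
    FRAIL: {
        "fraction": 8 / 60,
        "sl": (0.52, 0.17), "sc": (1.88, 0.09),
        "six_mwee": (11.10, 5.01), "six_mwd": (253.0, 118.0),
        "jchs_range": (3, 5),
    },
    PRE_FRAIL: {
        "fraction": 23 / 60,
        "sl": (0.61, 0.07), "sc": (2.15, 0.17),
        "six_mwee": (19.70, 4.58), "six_mwd": (385.0, 76.0),
        "jchs_range": (1, 2),
    },
    NON_FRAIL: {
        "fraction": 29 / 60,
        "sl": (0.67, 0.09), "sc": (2.12, 0.11),
        "six_mwee": (21.48, 4.40), "six_mwd": (430.0, 60.0),
        "jchs_range": (0, 0),
    },
}

_PARAMS = ("sl", "sc", "six_mwee", "six_mwd")
_JCHS_ITEMS = ("q_weight_loss", "q_exhaustion", "q_low_activity",
               "weak_handgrip", "slow_speed")


def simulate_cohort(
    n: int,
    group_specs: Optional[dict[str, dict]] = None,
    seed: int = 0,
    correlation: float = 0.4,
) -> pd.DataFrame:
    """Draw a synthetic cohort subject table with ground-truth group labels.

    Gait parameters are drawn from per-group Gaussians (defaults: the
    published cohort means/SDs) with a common pairwise correlation;
    frailty items are drawn so the item count matches each group's
    category.  Returns one row per subject with columns sl, sc, gv,
    six_mwee, six_mwd, the five item booleans, jchs_n and category.
    """
    specs = group_specs or DEFAULT_GROUP_SPECS
    if not -1.0 / (len(_PARAMS) - 1) < correlation < 1.0:
        raise ValueError(f"correlation {correlation} outside the valid range")
    rng = np.random.default_rng(seed)

    # largest-remainder apportionment of n across groups
    fracs = {g: spec["fraction"] for g, spec in specs.items()}
    total = sum(fracs.values())
    quotas = {g: n * f / total for g, f in fracs.items()}
    counts = {g: int(np.floor(qt)) for g, qt in quotas.items()}
    leftover = n - sum(counts.values())
    for g in sorted(quotas, key=lambda g: quotas[g] - counts[g], reverse=True)[:leftover]:
        counts[g] += 1
    if any(c < 2 for c in counts.values()):
        raise ValueError(f"every group needs n >= 2, got {counts}")

    corr = np.full((len(_PARAMS), len(_PARAMS)), correlation)
    np.fill_diagonal(corr, 1.0)
    chol = np.linalg.cholesky(corr)

    rows = []
    sid = 0
    for group, spec in specs.items():
        m = counts[group]
        mu = np.array([spec[p][0] for p in _PARAMS])
        sd = np.array([spec[p][1] for p in _PARAMS])
        zs = rng.standard_normal(size=(m, len(_PARAMS))) @ chol.T
        vals = mu + zs * sd
        lo, hi = spec["jchs_range"]
        for i in range(m):
            n_items = int(rng.integers(lo, hi + 1))
            which = rng.choice(len(_JCHS_ITEMS), size=n_items, replace=False)
            items = {item: (j in which) for j, item in enumerate(_JCHS_ITEMS)}
            row = {
                "subject_id": f"S{sid:04d}",
                "category": group,
                "sl": vals[i, 0], "sc": vals[i, 1],
                "gv": vals[i, 0] * vals[i, 1],
                "six_mwee": vals[i, 2], "six_mwd": vals[i, 3],
                "jchs_n": n_items,
            }
            row.update(items)
            rows.append(row)
            sid += 1
    return pd.DataFrame(rows)
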