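"""Gravity separation and Kalman smoothing of ankle accelerometer signals.

Raw ankle acceleration is the sum of a slowly-varying gravitational
component and the gait (motion) acceleration.  A second-order Butterworth
low-pass (cutoff 0.2 Hz at fs=50 Hz) isolates gravity per axis; subtracting
it leaves the gait acceleration, so gravity + motion reconstructs the input
exactly.  The motion signal is then smoothed with a constant-acceleration
Kalman filter whose state is (position, velocity, acceleration) and whose
only observation is the acceleration itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal

from .types import AccelTrace


@dataclass
class FilterCoeffs:
    """Second-order IIR low-pass in direct form.

    The recursion is ``y[n] = gain*(b0*x[n] + b1*x[n-1] + b2*x[n-2])
    - a1*y[n-1] - a2*y[n-2]``.  For a Butterworth low-pass the feed-forward
    pattern (b0, b1, b2) is proportional to (1, 2, 1) and the DC gain is
    exactly one.
    """

    b0: float
    b1: float
    b2: float
    a1: float
    a2: float
    gain: float
    fc: float
    fs: float

    def __post_init__(self) -> None:
        dc = (self.b0 + self.b1 + self.b2) * self.gain / (1.0 + self.a1 + self.a2)
        if abs(dc - 1.0) > 1e-9:
            raise ValueError(f"DC gain {dc} deviates from 1 by more than 1e-9")
        poles = np.roots([1.0, self.a1, self.a2])
        if np.any(np.abs(poles) >= 1.0):
            raise ValueError("unstable filter: pole on or outside the unit circle")

    @property
    def b(self) -> np.ndarray:
        """Normalized numerator, gain applied."""
        return self.gain * np.array([self.b0, self.b1, self.b2])

    @property
    def a(self) -> np.ndarray:
        return np.array([1.0, self.a1, self.a2])

    def response(self, freqs: np.ndarray) -> np.ndarray:
        """|H(f)| evaluated at frequencies [Hz]."""
        w = 2 * np.pi * np.asarray(freqs, dtype=float) / self.fs
        _, h = signal.freqz(self.b, self.a, worN=w)
        return np.abs(h)


def design_lowpass(fc: float, fs: float) -> FilterCoeffs:
    """Design the second-order Butterworth low-pass at cutoff fc for rate fs.

    Uses the bilinear transform at normalized cutoff wc = 2*fc/fs; the
    result has unit DC gain and its −3 dB point at fc.
    """
    if not 0 < fc < fs / 2:
        raise ValueError(f"fc must lie in (0, fs/2)=(0, {fs / 2}), got {fc}")
    b, a = signal.butter(2, 2.0 * fc / fs, btype="low")
    return FilterCoeffs(
        b0=b[0] / b[0], b1=b[1] / b[0], b2=b[2] / b[0],
        a1=a[1], a2=a[2], gain=b[0], fc=fc, fs=fs,
    )


def separate_gravity(
    trace: AccelTrace, coeffs: FilterCoeffs, zero_phase: bool = False
) -> tuple[AccelTrace, AccelTrace]:
    """Split a trace into (gravity, motion) per axis.

    Gravity is the low-pass of the raw signal; motion is the remainder, so
    ``gravity + motion == input`` at machine precision.  By default the
    filter is the causal recursion, with its state initialized to the
    steady state of the first second's mean (exact for constant inputs,
    and insensitive to the first sample's noise).  ``zero_phase=True``
    applies the same filter forward-backward instead, which removes the
    causal decay tail after low-frequency swings — used by the turn
    detector, not for the reported gait signals.
    """
    if len(trace) < 3:
        raise ValueError("trace shorter than 3 samples")
    if trace.fs != coeffs.fs:
        raise ValueError(f"trace fs={trace.fs} does not match filter fs={coeffs.fs}")
    zi = signal.lfilter_zi(coeffs.b, coeffs.a)
    head = max(1, min(len(trace), int(round(coeffs.fs))))
    grav = {}
    for axis in ("x", "y", "z"):
        raw = getattr(trace, axis)
        if zero_phase:
            g = signal.filtfilt(coeffs.b, coeffs.a, raw)
        else:
            g, _ = signal.lfilter(coeffs.b, coeffs.a, raw, zi=zi * raw[:head].mean())
        grav[axis] = g
    gravity = AccelTrace(
        t=trace.t, x=grav["x"], y=grav["y"], z=grav["z"],
        fs=trace.fs, sensor_id=trace.sensor_id, unit=trace.unit,
    )
    motion = AccelTrace(
        t=trace.t, x=trace.x - grav["x"], y=trace.y - grav["y"],
        z=trace.z - grav["z"], fs=trace.fs, sensor_id=trace.sensor_id,
        unit=trace.unit,
    )
    return gravity, motion


@dataclass
class KalmanParams:
    """Constant-acceleration Kalman model.

    State (position, velocity, acceleration) with transition
    ``F = [[1, dt, dt²/2], [0, 1, dt], [0, 0, 1]]`` and input/noise shape
    ``G = [dt²/2, dt, 1]ᵀ``; only the acceleration component is observed.
    ``q`` is the process-noise intensity (process covariance q·G·Gᵀ) and
    ``r`` the measurement-noise variance.
    """

    dt: float
    q: float = 1e-2
    r: float = 1.0
    x0: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        if not (self.dt > 0 and self.q > 0 and self.r > 0):
            raise ValueError("dt, q, r must all be positive")
        self.x0 = np.asarray(self.x0, dtype=float)
        if self.x0.shape != (3,):
            raise ValueError("x0 must have shape (3,)")

    @property
    def F(self) -> np.ndarray:
        dt = self.dt
        return np.array([[1.0, dt, dt * dt / 2], [0.0, 1.0, dt], [0.0, 0.0, 1.0]])

    @property
    def G(self) -> np.ndarray:
        dt = self.dt
        return np.array([dt * dt / 2, dt, 1.0])


def default_measurement_noise(z: np.ndarray) -> float:
    """Data-driven measurement-noise variance: var of the first difference / 2.

    For a signal x + white noise e, var(diff) ≈ 2·var(e) when the noise
    dominates sample-to-sample change, hence the factor 1/2.
    """
    z = np.asarray(z, dtype=float)
    if len(z) < 2:
        return 1.0
    v = float(np.var(np.diff(z), ddof=1)) / 2.0
    return v if v > 0 else 1.0


def kalman_smooth(
    motion_axis: np.ndarray, params: KalmanParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run the predict/update recursion over one motion-axis signal.

    Returns the full state history (position, velocity, smoothed
    acceleration), each the same length as the input.  Positions and
    velocities are diagnostic only — walking distance always comes from
    the lane geometry, never from double integration.
    """
    z = np.asarray(motion_axis, dtype=float)
    bad = np.flatnonzero(~np.isfinite(z))
    if bad.size:
        raise ValueError(f"non-finite sample at index {bad[0]}")
    n = len(z)
    F = params.F
    G = params.G
    Q = params.q * np.outer(G, G)
    r = params.r
    H = np.array([0.0, 0.0, 1.0])

    xs = np.empty((n, 3))
    x = params.x0.copy()
    P = np.zeros((3, 3))
    for k in range(n):
        # predict
        x = F @ x
        P = F @ P @ F.T + Q
        # update with the measured acceleration
        s = P[2, 2] + r
        K = P[:, 2] / s
        x = x + K * (z[k] - x[2])
        P = P - np.outer(K, P[2, :])
        xs[k] = x
    return xs[:, 0], xs[:, 1], xs[:, 2]


def smooth_motion(motion: AccelTrace, q: float = 1e-2,
                  r: Optional[float] = None) -> AccelTrace:
    """Kalman-smooth all three axes of a motion trace (acceleration output only)."""
    dt = 1.0 / motion.fs
    out = {}
    for axis in ("x", "y", "z"):
        zsig = getattr(motion, axis)
        r_axis = r if r is not None else default_measurement_noise(zsig)
        params = KalmanParams(dt=dt, q=q, r=r_axis)
        _, _, acc = kalman_smooth(zsig, params)
        out[axis] = acc
    return AccelTrace(
        t=motion.t, x=out["x"], y=out["y"], z=out["z"],
        fs=motion.fs, sensor_id=motion.sensor_id, unit=motion.unit,
    )
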