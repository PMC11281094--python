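"""The Walking Muscle Strength (WMS) index, sigmoid score, and 1–4 scale.

Stride length, cadence and walking energy expenditure co-vary along a
single axis in elderly walkers; the WMS index is the projection of a
subject onto that axis, expressed as a linear form
``WMS = 0.064·SL + 0.189·SC + 0.859·6MWEE + 1.554`` (published fit).  A
sigmoid ``S = 1/(1+exp(−a·(WMS−b)))`` with published a=1.198, b=18.388 —
calibrated so S=0.5 at the 400 m walking-distance boundary — maps the
index to (0,1), and the score is discretized into WMS1 (<0.01),
WMS2 (0.01–0.50), WMS3 (0.50–0.95) and WMS4 (>0.95).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy import optimize

ArrayLike = Union[float, np.ndarray]

PUBLISHED_COEFFS = (0.064, 0.189, 0.859)  # SL, SC, 6MWEE weights
PUBLISHED_INTERCEPT = 1.554
PUBLISHED_A = 1.198
PUBLISHED_B = 18.388
SCALE_BOUNDS = (0.01, 0.50, 0.95)


@dataclass
class WMSModel:
    """Linear WMS index plus (optionally) its sigmoid calibration.

    ``input_convention`` records whether the linear form consumes raw
    parameter values (m/step, step/s, kcal/h) or mean-normalized ones;
    the published model is raw.  A refit model may lack the sigmoid
    (``a``/``b`` None) until :func:`fit_sigmoid` supplies it.
    """

    w_sl: float
    w_sc: float
    w_ee: float
    intercept: float
    a: Optional[float] = None
    b: Optional[float] = None
    scale_bounds: tuple[float, float, float] = SCALE_BOUNDS
    input_convention: str = "raw"  # or "mean-normalized"
    provenance: str = "published"  # or "refit"
    r: Optional[float] = None      # line-fit correlation, refit models only
    means: Optional[tuple[float, float, float]] = None  # normalization means

    def __post_init__(self) -> None:
        if self.a is not None and not self.a > 0:
            raise ValueError(f"sigmoid slope a must be positive, got {self.a}")
        lo, mid, hi = self.scale_bounds
        if not (0 < lo < mid < hi < 1):
            raise ValueError(f"scale_bounds must be strictly increasing in (0,1), got {self.scale_bounds}")
        if self.input_convention not in ("raw", "mean-normalized"):
            raise ValueError(f"unknown input_convention {self.input_convention!r}")
        if self.provenance not in ("published", "refit"):
            raise ValueError(f"unknown provenance {self.provenance!r}")


def published_model() -> WMSModel:
    """The published WMS model: Eq.-12 coefficients and the fitted sigmoid."""
    return WMSModel(
        w_sl=PUBLISHED_COEFFS[0],
        w_sc=PUBLISHED_COEFFS[1],
        w_ee=PUBLISHED_COEFFS[2],
        intercept=PUBLISHED_INTERCEPT,
        a=PUBLISHED_A,
        b=PUBLISHED_B,
    )


def wms_index(model: WMSModel, sl: ArrayLike, sc: ArrayLike, ee: ArrayLike) -> ArrayLike:
    """Evaluate the linear WMS index (inputs on the model's convention)."""
    out = model.w_sl * np.asarray(sl) + model.w_sc * np.asarray(sc) \
        + model.w_ee * np.asarray(ee) + model.intercept
    return float(out) if np.ndim(out) == 0 else out


def wms_sigmoid(model: WMSModel, wms: ArrayLike) -> ArrayLike:
    """Sigmoid score S(WMS) = 1/(1+exp(−a·(WMS−b))) in (0, 1)."""
    if model.a is None or model.b is None:
        raise ValueError("model has no sigmoid calibration (a, b)")
    wms = np.asarray(wms, dtype=float)
    if not np.all(np.isfinite(wms)):
        raise ValueError("WMS must be finite")
    out = 1.0 / (1.0 + np.exp(-model.a * (wms - model.b)))
    return float(out) if np.ndim(out) == 0 else out


def wms_scale(s: ArrayLike, bounds: tuple[float, float, float] = SCALE_BOUNDS) -> ArrayLike:
    """Discretize a sigmoid score into the WMS 1–4 scale.

    Level 1: s < 0.01; level 2: 0.01 ≤ s < 0.50; level 3: 0.50 ≤ s ≤ 0.95;
    level 4: s > 0.95 (the upper bound is strict, so 0.95 itself is level 3).
    """
    s_arr = np.asarray(s, dtype=float)
    if np.any((s_arr <= 0) | (s_arr >= 1)):
        raise ValueError("sigmoid scores must lie strictly inside (0, 1)")
    lo, mid, hi = bounds
    level = np.select(
        [s_arr < lo, s_arr < mid, s_arr <= hi], [1, 2, 3], default=4
    )
    return int(level) if np.ndim(s) == 0 else level


def fit_wms_line(
    sl: np.ndarray,
    sc: np.ndarray,
    ee: np.ndarray,
    method: str = "tls",
    response: Optional[np.ndarray] = None,
) -> WMSModel:
    """Refit the WMS line on a cohort.

    Each parameter is normalized by its mean; ``method="tls"`` (default)
    takes the first principal axis of the normalized cloud (total least
    squares) and defines WMS as the scalar projection onto it, re-expressed
    as a linear form in the raw parameters.  ``method="ols"`` instead
    regresses an explicit ``response`` (e.g. walking distance) on the
    normalized parameters.  The fitted-line correlation ``r`` —
    sqrt(variance explained by the axis) for TLS, the multiple correlation
    for OLS — is stored on the model.
    """
    X = np.column_stack([
        np.asarray(sl, dtype=float),
        np.asarray(sc, dtype=float),
        np.asarray(ee, dtype=float),
    ])
    if X.shape[0] < 4:
        raise ValueError("need at least 4 subjects to fit the WMS line")
    means = X.mean(axis=0)
    if np.any(means <= 0):
        raise ValueError("parameter means must be positive for mean-normalization")
    Z = X / means  # mean-normalized; each column has mean 1
    Zc = Z - 1.0

    if method == "tls":
        _, svals, vt = np.linalg.svd(Zc, full_matrices=False)
        if svals[0] <= 1e-8 or (len(svals) > 1 and svals[1] / svals[0] > 1 - 1e-12):
            raise ValueError("degenerate cloud: principal axis undefined")
        v = vt[0]
        if v.sum() < 0:  # orient the axis so stronger walkers score higher
            v = -v
        var = svals ** 2
        r = float(np.sqrt(var[0] / var.sum()))
        weights = v / means
        intercept = -float(v.sum())
    elif method == "ols":
        if response is None:
            raise ValueError("method='ols' requires a response vector")
        y = np.asarray(response, dtype=float)
        A = np.column_stack([Zc, np.ones(len(y))])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        v = coef[:3]
        if not np.any(v):
            raise ValueError("degenerate regression: all coefficients zero")
        pred = A @ coef
        r = float(np.corrcoef(pred, y)[0, 1]) if np.ptp(pred) > 0 else 0.0
        weights = v / means
        intercept = float(coef[3] - v.sum())
    else:
        raise ValueError(f"unknown method {method!r}")

    return WMSModel(
        w_sl=float(weights[0]), w_sc=float(weights[1]), w_ee=float(weights[2]),
        intercept=intercept, a=None, b=None,
        input_convention="raw", provenance="refit", r=r,
        means=(float(means[0]), float(means[1]), float(means[2])),
    )


def fit_sigmoid(
    wms: np.ndarray,
    six_mwd: np.ndarray,
    threshold: float = 400.0,
    tol: float = 1e-10,
) -> tuple[float, float]:
    """Calibrate the sigmoid (a, b) against the walking-distance criterion.

    Subjects are labelled 1 when 6MWD ≥ threshold, else 0, and (a, b)
    minimize the sum of squared differences between S(WMS) and the labels
    (nonlinear least squares, a constrained positive).  Initialization:
    a₀ = 4/IQR(WMS), b₀ = median(WMS).
    """
    wms = np.asarray(wms, dtype=float)
    y = (np.asarray(six_mwd, dtype=float) >= threshold).astype(float)
    if len(np.unique(y)) < 2:
        raise ValueError("both label classes must be present to fit the sigmoid")

    iqr = float(np.subtract(*np.percentile(wms, [75, 25])))
    a0 = 4.0 / iqr if iqr > 0 else 1.0
    b0 = float(np.median(wms))

    def residuals(theta: np.ndarray) -> np.ndarray:
        a, b = theta
        return 1.0 / (1.0 + np.exp(-a * (wms - b))) - y

    res = optimize.least_squares(
        residuals, x0=[a0, b0],
        bounds=([1e-8, -np.inf], [np.inf, np.inf]),
        ftol=tol, xtol=tol, gtol=tol,
    )
    a, b = res.x
    return float(a), float(b)


def with_sigmoid(model: WMSModel, a: float, b: float) -> WMSModel:
    """Return a copy of a model with the sigmoid calibration attached."""
    return WMSModel(
        w_sl=model.w_sl, w_sc=model.w_sc, w_ee=model.w_ee,
        intercept=model.intercept, a=a, b=b,
        scale_bounds=model.scale_bounds,
        input_convention=model.input_convention,
        provenance=model.provenance, r=model.r, means=model.means,
    )


def model_to_dict(model: WMSModel) -> dict:
    """Serialize a model to a JSON-clean dict."""
    return {
        "w_sl": model.w_sl, "w_sc": model.w_sc, "w_ee": model.w_ee,
        "intercept": model.intercept, "a": model.a, "b": model.b,
        "scale_bounds": list(model.scale_bounds),
        "input_convention": model.input_convention,
        "provenance": model.provenance, "r": model.r,
        "means": list(model.means) if model.means is not None else None,
    }


def model_from_dict(data: dict) -> WMSModel:
    data = dict(data)
    data["scale_bounds"] = tuple(data.get("scale_bounds", SCALE_BOUNDS))
    if data.get("means") is not None:
        data["means"] = tuple(data["means"])
    return WMSModel(**data)
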