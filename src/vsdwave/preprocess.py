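"""Photobleaching correction and smoothing of membrane intensity traces.

Continuous illumination bleaches the dye, so raw membrane fluorescence decays
over the recording.  The decay is modelled as a second-order exponential
``F_bleach(t) = a*exp(b*t) + c*exp(d*t)`` with both rates constrained
non-positive; the trace is converted to dF/F by subtracting the fit and
dividing by it.  The normalized trace is then smoothed with a moving-average
filter (default 50 lines) before beat detection.

The bleach model is fitted to the full trace including beats; the resulting
bias is bounded by the beat duty cycle.  If the two-exponential fit fails,
the fitter falls back to a single exponential and finally to the trace mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .motion import MembraneTrace

logger = logging.getLogger(__name__)


class BleachFitError(RuntimeError):
    """The fitted bleach curve is unusable (non-positive somewhere)."""


@dataclass
class BleachFit:
    """A fitted photobleaching model ``a*exp(b*t) + c*exp(d*t)``."""

    a: float
    b: float
    c: float
    d: float
    curve: np.ndarray
    sse: float
    mode: str = "double"  # "double", "single" or "constant" fallback

    def __call__(self, t: np.ndarray) -> np.ndarray:
        return self.a * np.exp(self.b * t) + self.c * np.exp(self.d * t)


@dataclass
class NormalizedTrace:
    """A dF/F trace on a uniform time grid."""

    times: np.ndarray
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("normalized trace contains non-finite values")

    @property
    def line_period(self) -> float:
        return float(self.times[1] - self.times[0])


def _double_exp(t, a, b, c, d):
    return a * np.exp(b * t) + c * np.exp(d * t)


def _single_exp(t, a, b):
    return a * np.exp(b * t)


def _loglinear_seed(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Log-linear least squares seed for a*exp(b*t); b clipped to <= 0."""
    y = np.clip(y, 1e-9, None)
    slope, intercept = np.polyfit(t, np.log(y), 1)
    return float(np.exp(intercept)), float(min(slope, 0.0))


def correct_photobleach(
    trace: MembraneTrace | np.ndarray,
    times: np.ndarray | None = None,
    meta: dict | None = None,
) -> tuple[BleachFit, NormalizedTrace]:
    """Fit the two-exponential bleach model and normalize the trace to dF/F.

    The output is ``(F - fit) / fit``.  Accepts a tracked ``MembraneTrace``
    or a raw value array with a matching ``times`` grid.

    Raises
    ------
    ValueError
        For traces shorter than 100 lines or with non-positive intensities.
    BleachFitError
        If the fitted curve is not strictly positive (division undefined).
    """
    if isinstance(trace, MembraneTrace):
        y = np.asarray(trace.intensity, dtype=float)
        t = trace.times
        meta = {"membrane_id": trace.membrane_id, **(meta or {})}
    else:
        y = np.asarray(trace, dtype=float)
        if times is None:
            raise ValueError("times grid required for array input")
        t = np.asarray(times, dtype=float)
    if y.size < 100:
        raise ValueError("need at least 100 lines to fit the bleach model")
    if y.min() <= 0:
        raise ValueError("trace intensities must be strictly positive")

    # two-timescale seeding: slow component from the last third, fast from
    # the residual over the first third
    third = y.size // 3
    c0, d0 = _loglinear_seed(t[-third:], y[-third:])
    resid = y[:third] - c0 * np.exp(d0 * t[:third])
    if np.max(resid) > 0:
        a0, b0 = _loglinear_seed(t[:third], np.clip(resid, 1e-9, None))
    else:
        a0, b0 = 0.5 * float(np.mean(y)), -0.01

    fit = None
    try:
        popt, _ = curve_fit(
            _double_exp,
            t,
            y,
            p0=(max(a0, 1e-6), b0, max(c0, 1e-6), d0),
            bounds=((0.0, -np.inf, 0.0, -np.inf), (np.inf, 0.0, np.inf, 0.0)),
            maxfev=5000,
        )
        curve = _double_exp(t, *popt)
        fit = BleachFit(*popt, curve=curve, sse=float(np.sum((y - curve) ** 2)))
    except RuntimeError:
        logger.warning("double-exponential bleach fit failed; trying single")
    if fit is None:
        try:
            popt, _ = curve_fit(
                _single_exp,
                t,
                y,
                p0=(max(float(np.mean(y)), 1e-6), -0.01),
                bounds=((0.0, -np.inf), (np.inf, 0.0)),
                maxfev=5000,
            )
            curve = _single_exp(t, *popt)
            fit = BleachFit(
                popt[0], popt[1], 0.0, 0.0, curve=curve,
                sse=float(np.sum((y - curve) ** 2)), mode="single",
            )
        except RuntimeError:
            logger.warning("single-exponential bleach fit failed; using mean")
            mean = float(np.mean(y))
            fit = BleachFit(
                mean, 0.0, 0.0, 0.0, curve=np.full_like(y, mean),
                sse=float(np.sum((y - mean) ** 2)), mode="constant",
            )

    if fit.curve.min() <= 0:
        raise BleachFitError("invalid bleach model: fitted curve not positive")

    normalized = NormalizedTrace(
        times=t,
        values=(y - fit.curve) / fit.curve,
        meta={**(meta or {}), "bleach_mode": fit.mode},
    )
    return fit, normalized


def smooth(trace: NormalizedTrace, window: int = 50) -> NormalizedTrace:
    """Centred moving average; edges use shrinking windows.

    The window is used exactly as given (even windows place the extra sample
    before the centre), so a unit impulse maps to a boxcar of height
    ``1/window`` spanning ``window`` lines.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    n = trace.values.size
    if window >= n:
        raise ValueError("window must be smaller than the trace length")
    from .beats import estimate_noise_sd

    noise_sd = estimate_noise_sd(trace.values)
    left = window // 2
    right = window - 1 - left
    csum = np.concatenate(([0.0], np.cumsum(trace.values)))
    idx = np.arange(n)
    lo = np.clip(idx - left, 0, n)
    hi = np.clip(idx + right + 1, 0, n)
    out = (csum[hi] - csum[lo]) / (hi - lo)
    return NormalizedTrace(
        times=trace.times,
        values=out,
        meta={**trace.meta, "smoothing_window": window, "noise_sd_raw": noise_sd},
    )
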