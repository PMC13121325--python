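"""Shared dense-grid numerics for compartmental model evaluation.

All kinetic models are evaluated on a uniform dense time grid (default 1 s
step) on which the sampled input curve is treated as piecewise linear. The
exponential convolution is computed by a first-order recursion that is exact
for piecewise-linear inputs, and model predictions are averaged over each
frame's duration before comparison with measured frame values.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import lfilter

from .petdata import FrameSchedule, InputFunction

__all__ = [
    "dense_grid",
    "resample_dense",
    "exp_conv",
    "running_integral",
    "frame_average",
    "curve_auc",
]


def dense_grid(schedule: FrameSchedule, dt_s: float = 1.0) -> np.ndarray:
    """Uniform grid in seconds from 0 to the end of the last frame."""
    end = float(schedule.end_s[-1])
    n = int(np.ceil(end / dt_s)) + 1
    return np.arange(n) * dt_s


def resample_dense(inp: InputFunction | tuple, t_dense_s: np.ndarray,
                   delay_s: float = 0.0) -> np.ndarray:
    """Sample an input curve on a dense grid, optionally delayed.

    The curve is linearly interpolated through (0, 0) and its frame-midpoint
    samples; values are held constant beyond the last sample and are zero
    before time 0. A positive ``delay_s`` moves the curve later in time
    (tissue sees ``C_A(t - delay)``).
    """
    if isinstance(inp, InputFunction):
        t, v = inp.schedule.mid_s, inp.values
    else:
        t, v = inp
    t = np.asarray(t, float)
    v = np.asarray(v, float)
    if t[0] > 0:
        t = np.concatenate([[0.0], t])
        v = np.concatenate([[0.0], v])
    query = t_dense_s - delay_s
    out = np.interp(query, t, v)
    out[query < t[0]] = 0.0
    return out


def exp_conv(c_dense: np.ndarray, k_per_min: float, dt_s: float) -> np.ndarray:
    """``∫₀ᵗ c(s)·e^{−k(t−s)} ds`` on the dense grid, in minutes.

    Exact for piecewise-linear ``c``; ``k`` is per minute and the result
    carries units of (activity·min).
    """
    dt = dt_s / 60.0  # minutes
    c = np.asarray(c_dense, float)
    a, b = c[:-1], c[1:]
    if k_per_min > 1e-12:
        e = np.exp(-k_per_min * dt)
        # contribution of one linear segment, evaluated at its right edge
        g = a * (1.0 - e) / k_per_min + (b - a) * (dt - (1.0 - e) / k_per_min) / (k_per_min * dt)
        out = np.empty_like(c)
        out[0] = 0.0
        out[1:] = lfilter([1.0], [1.0, -e], g)
    else:
        out = running_integral(c, dt_s)
    return out


def running_integral(c_dense: np.ndarray, dt_s: float) -> np.ndarray:
    """Cumulative trapezoid integral in minute units."""
    c = np.asarray(c_dense, float)
    dt = dt_s / 60.0
    seg = 0.5 * (c[:-1] + c[1:]) * dt
    out = np.empty_like(c)
    out[0] = 0.0
    out[1:] = np.cumsum(seg)
    return out


def frame_average(dense_values: np.ndarray, t_dense_s: np.ndarray,
                  schedule: FrameSchedule) -> np.ndarray:
    """Average the dense curve over each frame's duration.

    Uses the exact integral of the piecewise-linear dense curve so the
    result is independent of how frame edges align with grid points.
    """
    dt_s = t_dense_s[1] - t_dense_s[0]
    cum = running_integral(dense_values, dt_s) * 60.0  # activity·seconds
    lo = np.interp(schedule.start_s, t_dense_s, cum)
    hi = np.interp(schedule.end_s, t_dense_s, cum)
    return (hi - lo) / schedule.duration_s


def curve_auc(t_s: np.ndarray, values: np.ndarray) -> float:
    """Trapezoid area under a sampled curve, in kBq/mL·min."""
    return float(np.trapezoid(values, np.asarray(t_s, float) / 60.0))
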