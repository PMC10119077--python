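"""Shared numerical kernels for compartment-model evaluation.

The workhorse is the convolution of a piecewise-linear input curve with
a decaying exponential, computed exactly per linear segment (closed-form
integrals) and propagated with the one-step recursion

    y(t_{i+1}) = e^{-k dt} y(t_i) + beta0 f_i + beta1 f_{i+1},

which on a uniform grid is a first-order IIR filter and runs at C speed
through scipy.signal.lfilter.  This is exact for piecewise-linear inputs
— no quadrature error accumulates — so accuracy is limited only by how
finely the input curve is sampled.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import lfilter

from .timebase import FrameSchedule

__all__ = ["expconv_uniform", "frame_average", "model_grid", "cumulative_frame_integral"]


def expconv_uniform(f: np.ndarray, dt: float, k: float) -> np.ndarray:
    """``y(t_n) = int_0^{t_n} exp(-k (t_n - s)) f(s) ds`` on a uniform grid.

    ``f`` holds samples of a piecewise-linear function at spacing ``dt``;
    ``k >= 0``.  Returns ``y`` at the same nodes (y[0] = 0).
    """
    f = np.asarray(f, dtype=float)
    if f.ndim != 1:
        raise ValueError("f must be 1-D")
    if k < 0:
        raise ValueError("decay rate k must be non-negative")
    n = f.size
    if n < 2:
        return np.zeros(n)
    kdt = k * dt
    if kdt < 1e-8:
        # k -> 0 limit: running trapezoid
        a = 1.0 - kdt
        beta0 = beta1 = dt / 2.0
    else:
        a = np.exp(-kdt)
        i0 = -np.expm1(-kdt) / k          # int_0^dt e^{-k(dt-u)} du
        i1 = (dt - i0) / k                # int_0^dt e^{-k(dt-u)} u du
        beta0 = i0 - i1 / dt
        beta1 = i1 / dt
    b = beta0 * f[:-1] + beta1 * f[1:]
    y = lfilter([1.0], [1.0, -a], b)
    return np.concatenate([[0.0], y])


def model_grid(schedule: FrameSchedule, dt_min: float = 0.05) -> np.ndarray:
    """Uniform evaluation grid (minutes) from 0 to the last frame end."""
    end = schedule.ends_min[-1]
    n = int(round(end / dt_min))
    return np.linspace(0.0, n * dt_min, n + 1)


def frame_average(
    grid_min: np.ndarray, curve: np.ndarray, schedule: FrameSchedule
) -> np.ndarray:
    """Time-average of a sampled curve over each frame interval.

    The curve is treated as piecewise linear between grid nodes; frame
    boundaries need not coincide with nodes.
    """
    grid = np.asarray(grid_min, dtype=float)
    curve = np.asarray(curve, dtype=float)
    starts, ends = schedule.starts_min, schedule.ends_min
    if grid[0] > starts[0] + 1e-12 or grid[-1] < ends[-1] - 1e-9:
        raise ValueError(
            f"grid [{grid[0]:.3f}, {grid[-1]:.3f}] min does not cover the "
            f"schedule [{starts[0]:.3f}, {ends[-1]:.3f}] min"
        )
    out = np.empty(len(schedule))
    for i, (s, e) in enumerate(zip(starts, ends)):
        lo = np.searchsorted(grid, s, side="right")
        hi = np.searchsorted(grid, e, side="left")
        inner = grid[lo:hi]
        nodes = np.concatenate([[s], inner, [e]])
        vals = np.concatenate(
            [[np.interp(s, grid, curve)], curve[lo:hi], [np.interp(e, grid, curve)]]
        )
        out[i] = np.trapezoid(vals, nodes) / (e - s)
    return out


def cumulative_frame_integral(
    schedule: FrameSchedule, values: np.ndarray
) -> np.ndarray:
    """``int_0^{midtime_i} C(t) dt`` from frame-averaged TAC values.

    Within frames the frame average times the elapsed duration is exact.
    An inter-part gap is bridged with a local cubic Hermite segment
    through the neighbouring frame midtimes (secant-estimated slopes),
    which tracks a TAC that peaks inside the gap far better than a
    chord; with too few neighbouring frames it falls back to the
    trapezoid.  Before the first frame the curve rises linearly from
    (0, 0).
    """
    values = np.asarray(values, dtype=float)
    starts, ends = schedule.starts_min, schedule.ends_min
    durs = schedule.durations_min
    mid = (starts + ends) / 2.0
    n = len(schedule)
    cum_at_start = np.empty(n)
    running = 0.0
    prev_end = 0.0
    prev_val = 0.0
    for j in range(n):
        gap = starts[j] - prev_end
        if gap > 1e-12:
            if j == 0:  # leading ramp from injection
                running += 0.5 * values[0] * gap
            else:
                running += _gap_integral(j, mid, values, prev_end, starts[j])
        cum_at_start[j] = running
        running += values[j] * durs[j]
        prev_end = ends[j]
        prev_val = values[j]
    return cum_at_start + values * (durs / 2.0)


def _gap_integral(
    j: int, mid: np.ndarray, values: np.ndarray, t_lo: float, t_hi: float
) -> float:
    """Integral of the bridged curve over an inter-part gap [t_lo, t_hi]."""
    n = values.size
    if j < 2 or j > n - 2:
        return 0.5 * (values[j - 1] + values[j]) * (t_hi - t_lo)
    from scipy.interpolate import CubicHermiteSpline

    t = mid[j - 2 : j + 2]
    v = values[j - 2 : j + 2]
    d = np.gradient(v, t)
    seg = CubicHermiteSpline(t[1:3], v[1:3], d[1:3])
    return float(seg.antiderivative()(t_hi) - seg.antiderivative()(t_lo))
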