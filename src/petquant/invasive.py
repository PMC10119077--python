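"""Arterial-input kinetic models: 1TC, 2TC, and Logan graphical analysis.

The measured PET signal in a region mixes tissue and blood activity.
With fractional blood volume Vb the operational equation is

    PET(t) = Vb * Cwb(t) + (1 - Vb) * C_T(t)

where Cwb is whole blood and C_T the tissue response to the arterial
input function.  For the one-tissue compartment (1TC) model

    C_T(t) = K1 * int_0^t exp(-k2 (t - s)) AIF(s) ds,      Vt = K1/k2,

and for the serial two-tissue (2TC) model the response is a sum of two
such exponential modes with Vt = (K1/k2) (1 + k3/k4).  The Logan plot
turns the late-time behaviour into a straight line whose slope is Vt.
Model comparison uses the Akaike information criterion on the weighted
residual sum of squares.

Predicted frame values are time-averages of PET(t) over each frame
interval, matching how a scanner integrates counts within a frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import linregress

from ._numerics import (
    cumulative_frame_integral,
    expconv_uniform,
    frame_average,
    model_grid,
)
from .blood import FitFailureError, InputFunction
from .timebase import DecayConstants, FrameSchedule, frame_midtimes

__all__ = [
    "OneTCParams",
    "TwoTCParams",
    "GraphicalResult",
    "GofStats",
    "forward_1tc",
    "forward_2tc",
    "fit_1tc",
    "fit_2tc",
    "logan_vt",
    "aic",
    "dvr_from_vt",
    "default_frame_weights",
]

# Fit bounds sized to observed rate-constant magnitudes plus headroom.
_K1_BOUNDS = (0.0, 10.0)
_K2_BOUNDS = (1e-4, 1.0)
_K34_BOUNDS = (0.0, 1.0)
_VB_BOUNDS = (0.0, 0.2)

_DT_DEFAULT = 0.05  # minutes; model evaluation grid spacing


@dataclass(frozen=True)
class OneTCParams:
    """One-tissue compartment parameters; Vt = K1/k2."""

    K1: float  # mL/(min*mL)
    k2: float  # 1/min
    Vb: float = 0.0

    def __post_init__(self) -> None:
        if self.K1 < 0:
            raise ValueError("K1 must be non-negative")
        if self.k2 <= 0:
            raise ValueError("k2 must be positive")
        if not (0.0 <= self.Vb <= 0.2):
            raise ValueError("Vb must lie in [0, 0.2]")

    @property
    def Vt(self) -> float:
        return self.K1 / self.k2


@dataclass(frozen=True)
class TwoTCParams:
    """Two-tissue compartment parameters; Vt = (K1/k2)(1 + k3/k4)."""

    K1: float
    k2: float
    k3: float
    k4: float
    Vb: float = 0.0
    identifiability_flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if min(self.K1, self.k3, self.k4) < 0:
            raise ValueError("rate constants must be non-negative")
        if self.k2 <= 0:
            raise ValueError("k2 must be positive")
        if not (0.0 <= self.Vb <= 0.2):
            raise ValueError("Vb must lie in [0, 0.2]")

    @property
    def Vt(self) -> float:
        if self.k4 <= 0:
            raise ValueError("Vt undefined with k4 = 0")
        return (self.K1 / self.k2) * (1.0 + self.k3 / self.k4)


@dataclass(frozen=True)
class GraphicalResult:
    """Logan-plot linear segment: slope (Vt), intercept, fit window."""

    Vt: float
    intercept: float
    t_star: float
    n_points: int
    r_squared: float

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValueError("a graphical fit needs at least 3 points")
        if not (-1e-9 <= self.r_squared <= 1 + 1e-9):
            raise ValueError("R^2 out of [0, 1]")


@dataclass(frozen=True)
class GofStats:
    ssr: float
    n: int
    n_params: int
    aic: float


def aic(ssr: float, n: int, n_params: int) -> GofStats:
    """Akaike information criterion, AIC = n ln(SSR/n) + 2k."""
    if ssr <= 0:
        raise ValueError("AIC undefined for SSR <= 0 (perfect fit guard)")
    if n <= n_params:
        raise ValueError("need more data points than parameters")
    value = n * math.log(ssr / n) + 2 * n_params
    return GofStats(ssr=float(ssr), n=int(n), n_params=int(n_params), aic=value)


def default_frame_weights(
    schedule: FrameSchedule, constants: DecayConstants = DecayConstants()
) -> np.ndarray:
    """Count-statistics surrogate weights, w_j = dt_j * exp(-2 lambda t_j).

    Long late frames of a decayed tracer carry fewer true counts; this
    standard weighting downweights them accordingly.  Normalised to mean
    1 so that absolute SSR scales stay comparable across schedules.
    """
    mid = frame_midtimes(schedule)
    w = schedule.durations_min * np.exp(-2.0 * constants.lam * mid)
    return w / np.mean(w)


def _resample(aif: InputFunction, cwb_fun, grid: np.ndarray):
    if aif.grid_min[-1] < grid[-1] - 1e-6:
        raise ValueError(
            f"input-function grid ends at {aif.grid_min[-1]:.1f} min, "
            f"schedule needs {grid[-1]:.1f} min"
        )
    a = np.interp(grid, aif.grid_min, aif.aif)
    cwb = cwb_fun(grid) if cwb_fun is not None else np.interp(
        grid, aif.grid_min, aif.cwb
    )
    return a, cwb


def forward_1tc(
    params: OneTCParams,
    aif: InputFunction,
    cwb_fun: Callable[[np.ndarray], np.ndarray] | None,
    schedule: FrameSchedule,
    dt_min: float = _DT_DEFAULT,
) -> np.ndarray:
    """Frame-averaged 1TC model prediction (kBq/mL per frame)."""
    grid = model_grid(schedule, dt_min)
    a, cwb = _resample(aif, cwb_fun, grid)
    ct = params.K1 * expconv_uniform(a, dt_min, params.k2)
    pet = params.Vb * cwb + (1.0 - params.Vb) * ct
    return frame_average(grid, pet, schedule)


def forward_2tc(
    params: TwoTCParams,
    aif: InputFunction,
    cwb_fun: Callable[[np.ndarray], np.ndarray] | None,
    schedule: FrameSchedule,
    dt_min: float = _DT_DEFAULT,
) -> np.ndarray:
    """Frame-averaged 2TC model prediction via its bi-exponential impulse response.

    The serial system dC1/dt = K1 AIF - (k2+k3) C1 + k4 C2,
    dC2/dt = k3 C1 - k4 C2 has eigen-rates

        alpha_{1,2} = [(k2+k3+k4) -/+ sqrt((k2+k3+k4)^2 - 4 k2 k4)] / 2

    and C_T = C1 + C2 is a weighted sum of two exponential convolutions.
    """
    grid = model_grid(schedule, dt_min)
    a, cwb = _resample(aif, cwb_fun, grid)
    k2, k3, k4 = params.k2, params.k3, params.k4
    s = k2 + k3 + k4
    disc = math.sqrt(max(s * s - 4.0 * k2 * k4, 0.0))
    a1 = (s - disc) / 2.0
    a2 = (s + disc) / 2.0
    if disc < 1e-12:  # degenerate equal roots; perturb infinitesimally
        a1 = max(a1 - 1e-9, 0.0)
        a2 = a2 + 1e-9
        disc = a2 - a1
    w1 = (k3 + k4 - a1) / disc
    w2 = (a2 - k3 - k4) / disc
    ct = params.K1 * (
        w1 * expconv_uniform(a, dt_min, a1) + w2 * expconv_uniform(a, dt_min, a2)
    )
    pet = params.Vb * cwb + (1.0 - params.Vb) * ct
    return frame_average(grid, pet, schedule)


def _wls_fit(residual_fun, starts, bounds):
    """Multi-start bounded least squares; returns the best result or raises."""
    best, diagnostics = None, []
    for x0 in starts:
        try:
            res = least_squares(residual_fun, x0, bounds=bounds, method="trf")
        except Exception as exc:  # pragma: no cover
            diagnostics.append((tuple(x0), repr(exc)))
            continue
        diagnostics.append((tuple(x0), res.cost, res.status))
        if res.status > 0 and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise FitFailureError("kinetic fit failed from all starts", diagnostics)
    return best


def fit_1tc(
    tac_values: np.ndarray,
    aif: InputFunction,
    cwb_fun: Callable[[np.ndarray], np.ndarray] | None,
    schedule: FrameSchedule,
    weights: np.ndarray | None = None,
    dt_min: float = _DT_DEFAULT,
) -> tuple[OneTCParams, GofStats]:
    """Weighted least-squares 1TC fit of one regional TAC."""
    y = np.asarray(tac_values, dtype=float)
    if len(schedule) < 6:
        raise ValueError("need at least 6 frames for a 1TC fit")
    if y.shape != (len(schedule),):
        raise ValueError("TAC length does not match schedule")
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != y.shape:
        raise ValueError("weights length does not match frames")
    sw = np.sqrt(w)

    grid = model_grid(schedule, dt_min)
    a, cwb = _resample(aif, cwb_fun, grid)
    cwb_frames = frame_average(grid, cwb, schedule)

    def model(x):
        k1, k2, vb = x
        ct = k1 * expconv_uniform(a, dt_min, k2)
        ct_frames = frame_average(grid, ct, schedule)
        return vb * cwb_frames + (1.0 - vb) * ct_frames

    def residuals(x):
        return sw * (model(x) - y)

    starts = [
        (k1, k2, vb)
        for k1, k2, vb in product((0.5, 2.0), (0.005, 0.05), (0.02, 0.08))
    ]
    lo = (_K1_BOUNDS[0], _K2_BOUNDS[0], _VB_BOUNDS[0])
    hi = (_K1_BOUNDS[1], _K2_BOUNDS[1], _VB_BOUNDS[1])
    best = _wls_fit(residuals, starts, (lo, hi))
    params = OneTCParams(K1=float(best.x[0]), k2=float(best.x[1]), Vb=float(best.x[2]))
    ssr = float(np.sum((model(best.x) - y) ** 2 * w))
    return params, aic(max(ssr, 1e-300), y.size, 3)


def fit_2tc(
    tac_values: np.ndarray,
    aif: InputFunction,
    cwb_fun: Callable[[np.ndarray], np.ndarray] | None,
    schedule: FrameSchedule,
    weights: np.ndarray | None = None,
    dt_min: float = _DT_DEFAULT,
) -> tuple[TwoTCParams, GofStats]:
    """Weighted least-squares 2TC fit; flags weakly identified k3/k4.

    With slow tracers the binding rates often collapse to a bound or the
    two eigen-modes merge; such fits are returned but carry flags in
    ``identifiability_flags`` rather than being silently trusted.
    """
    y = np.asarray(tac_values, dtype=float)
    if len(schedule) < 6:
        raise ValueError("need at least 6 frames for a 2TC fit")
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    sw = np.sqrt(w)

    grid = model_grid(schedule, dt_min)
    a, cwb = _resample(aif, cwb_fun, grid)
    cwb_frames = frame_average(grid, cwb, schedule)

    def model(x):
        k1, k2, k3, k4, vb = x
        s = k2 + k3 + k4
        disc = math.sqrt(max(s * s - 4.0 * k2 * k4, 1e-24))
        a1 = (s - disc) / 2.0
        a2 = (s + disc) / 2.0
        w1 = (k3 + k4 - a1) / disc
        w2 = (a2 - k3 - k4) / disc
        ct = k1 * (
            w1 * expconv_uniform(a, dt_min, a1) + w2 * expconv_uniform(a, dt_min, a2)
        )
        ct_frames = frame_average(grid, ct, schedule)
        return vb * cwb_frames + (1.0 - vb) * ct_frames

    def residuals(x):
        return sw * (model(x) - y)

    starts = [
        (1.0, 0.02, k3, k4, 0.03)
        for k3, k4 in product((0.005, 0.05), (0.005, 0.05))
    ] + [
        (0.5, 0.1, k3, k4, 0.03)
        for k3, k4 in product((0.01, 0.1), (0.01, 0.1))
    ]
    lo = (_K1_BOUNDS[0], _K2_BOUNDS[0], _K34_BOUNDS[0], _K34_BOUNDS[0], _VB_BOUNDS[0])
    hi = (_K1_BOUNDS[1], _K2_BOUNDS[1], _K34_BOUNDS[1], _K34_BOUNDS[1], _VB_BOUNDS[1])
    best = _wls_fit(residuals, starts, (lo, hi))
    k1, k2, k3, k4, vb = (float(v) for v in best.x)

    flags = []
    if k3 < 1e-6 or abs(k3 - _K34_BOUNDS[1]) < 1e-6:
        flags.append("k3_at_bound")
    if k4 < 1e-6 or abs(k4 - _K34_BOUNDS[1]) < 1e-6:
        flags.append("k4_at_bound")
    s = k2 + k3 + k4
    if s * s - 4.0 * k2 * k4 < 1e-10 * s * s:
        flags.append("degenerate_eigenrates")
    params = TwoTCParams(
        K1=k1, k2=k2, k3=k3, k4=k4, Vb=vb, identifiability_flags=tuple(flags)
    )
    ssr = float(np.sum((model(best.x) - y) ** 2 * w))
    return params, aic(max(ssr, 1e-300), y.size, 5)


def logan_vt(
    tac_values: np.ndarray,
    schedule: FrameSchedule,
    aif: InputFunction,
    t_star: float = 60.0,
) -> GraphicalResult:
    """Logan graphical estimate of Vt from the late linear segment.

    Transformed coordinates, per frame end-time T (frame midtimes used):
    y = int_0^T C_T / C_T(T), x = int_0^T AIF / C_T(T); the slope of the
    late (midtime > t_star) points estimates Vt.
    """
    y_tac = np.asarray(tac_values, dtype=float)
    mid = frame_midtimes(schedule)
    if t_star >= mid[-1]:
        raise ValueError(f"t_star = {t_star} min lies beyond the last frame")
    sel = mid > t_star
    if np.count_nonzero(sel) < 3:
        raise ValueError("need at least 3 frames beyond t_star")
    if np.any(y_tac[sel] <= 0):
        raise ValueError("non-positive TAC values in the Logan window")
    int_tac = cumulative_frame_integral(schedule, y_tac)
    cum_aif = np.concatenate(
        [[0.0], np.cumsum(np.diff(aif.grid_min) * (aif.aif[1:] + aif.aif[:-1]) / 2.0)]
    )
    int_aif = np.interp(mid, aif.grid_min, cum_aif)
    xs = int_aif[sel] / y_tac[sel]
    ys = int_tac[sel] / y_tac[sel]
    reg = linregress(xs, ys)
    return GraphicalResult(
        Vt=float(reg.slope),
        intercept=float(reg.intercept),
        t_star=float(t_star),
        n_points=int(np.count_nonzero(sel)),
        r_squared=float(reg.rvalue**2),
    )


def select_t_star(
    tac_values: np.ndarray,
    schedule: FrameSchedule,
    aif: InputFunction,
    max_rel_deviation: float = 0.10,
    candidates: Sequence[float] | None = None,
) -> float:
    """Earliest t* whose Logan points all stay within a relative deviation
    of the line fitted to them (max-deviation criterion); off by default
    in the fitting entry points."""
    mid = frame_midtimes(schedule)
    cands = candidates if candidates is not None else [float(t) for t in mid[:-3]]
    for t0 in cands:
        sel = mid > t0
        if np.count_nonzero(sel) < 3:
            break
        try:
            res = logan_vt(tac_values, schedule, aif, t_star=t0)
        except ValueError:
            continue
        y_tac = np.asarray(tac_values, dtype=float)
        int_tac = cumulative_frame_integral(schedule, y_tac)
        cum_aif = np.concatenate(
            [[0.0],
             np.cumsum(np.diff(aif.grid_min) * (aif.aif[1:] + aif.aif[:-1]) / 2.0)]
        )
        int_aif = np.interp(mid, aif.grid_min, cum_aif)
        xs = int_aif[sel] / y_tac[sel]
        ys = int_tac[sel] / y_tac[sel]
        pred = res.Vt * xs + res.intercept
        if np.all(np.abs(pred - ys) <= max_rel_deviation * np.abs(ys)):
            return float(t0)
    return float(cands[-1]) if len(cands) else float(mid[-4])


def dvr_from_vt(vt_roi: float, vt_ref: float) -> float:
    """Distribution volume ratio, Vt(ROI) / Vt(reference)."""
    if vt_ref <= 0:
        raise ValueError("reference Vt must be positive")
    return vt_roi / vt_ref
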