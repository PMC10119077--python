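"""Reference-tissue quantification: SRTM and the Logan reference plot.

Both methods avoid arterial sampling by using a region essentially
devoid of specific binding as a surrogate input.  SRTM assumes target
and reference kinetics are each well described by one tissue
compartment with a common non-displaceable distribution volume:

    C_T(t) = R1 Cref(t) + (k2 - R1 k2a) Cref(t) (x) exp(-k2a t),

with k2a = k2 / (1 + BP), R1 the relative delivery, and BP the binding
potential; DVR = BP + 1.  The Logan reference plot regresses

    int_0^T C_T / C_T(T)   on   [int_0^T Cref + Cref(T)/k2'] / C_T(T)

for late times; the slope is DVR directly.  The Cref/k2' term is
negligible for slowly clearing tracers at late t* and is omitted by
default (k2_prime=None).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import linregress

from ._numerics import cumulative_frame_integral, expconv_uniform, frame_average, model_grid
from .blood import FitFailureError
from .invasive import GofStats, aic
from .timebase import FrameSchedule, frame_midtimes

__all__ = ["SRTMResult", "LREFResult", "forward_srtm", "fit_srtm", "logan_ref"]

_DT_DEFAULT = 0.05

# Basis grid: 200 log-spaced k2a values spanning slow to fast washout.
_K2A_GRID = np.logspace(np.log10(1e-3), np.log10(1.0), 200)

# Plausibility cap on the binding potential: solutions with essentially
# no washout (k2 -> 0) otherwise run away to arbitrarily large BP.
_BP_MAX = 15.0


@dataclass(frozen=True)
class SRTMResult:
    R1: float
    k2: float
    BP: float
    gof: GofStats

    def __post_init__(self) -> None:
        if self.k2 <= 0:
            raise ValueError("fitted k2 must be positive")

    @property
    def DVR(self) -> float:
        return self.BP + 1.0

    @property
    def k2a(self) -> float:
        return self.k2 / (1.0 + self.BP)


@dataclass(frozen=True)
class LREFResult:
    DVR: float
    intercept: float
    t_star: float
    k2_prime: float | None
    n_points: int
    r_squared: float

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValueError("a graphical fit needs at least 3 points")

    @property
    def BP(self) -> float:
        return self.DVR - 1.0


def forward_srtm(
    R1: float,
    k2: float,
    BP: float,
    cref_fun: Callable[[np.ndarray], np.ndarray],
    schedule: FrameSchedule,
    dt_min: float = _DT_DEFAULT,
) -> np.ndarray:
    """Frame-averaged SRTM model prediction."""
    if BP <= -1:
        raise ValueError("BP must exceed -1")
    grid = model_grid(schedule, dt_min)
    cref = np.asarray(cref_fun(grid), dtype=float)
    k2a = k2 / (1.0 + BP)
    ct = R1 * cref + (k2 - R1 * k2a) * expconv_uniform(cref, dt_min, k2a)
    return frame_average(grid, ct, schedule)


def _cref_interp(schedule: FrameSchedule, ref_values: np.ndarray):
    """Continuous reference curve through (midtime, frame value) nodes,
    anchored at (0, 0) and held constant past the last midtime."""
    mid = frame_midtimes(schedule)
    nodes = np.concatenate([[0.0], mid])
    vals = np.concatenate([[0.0], np.asarray(ref_values, dtype=float)])
    return lambda t: np.interp(np.asarray(t, dtype=float), nodes, vals)


def fit_srtm(
    tac_roi: np.ndarray,
    tac_ref: np.ndarray,
    schedule: FrameSchedule,
    weights: np.ndarray | None = None,
    dt_min: float = _DT_DEFAULT,
    refine: bool = True,
) -> SRTMResult:
    """Basis-function SRTM fit of one target region against a reference TAC.

    For each candidate k2a the model is linear in (R1, k2 - R1*k2a), so a
    weighted linear solve per basis plus a 1-D search over k2a is convex
    per basis and robust.  A local nonlinear polish of (R1, k2, BP) from
    the best basis solution is applied by default to remove the residual
    k2a grid-quantisation error.
    """
    y = np.asarray(tac_roi, dtype=float)
    ref = np.asarray(tac_ref, dtype=float)
    if y.shape != (len(schedule),) or ref.shape != y.shape:
        raise ValueError("ROI/reference TACs must match the schedule length")
    mid = frame_midtimes(schedule)
    # noise can push tiny early frames negative; the uptake-phase and late
    # frames that actually constrain the fit must stay positive
    if np.any(ref[mid > 5.0] <= 0):
        raise ValueError("reference TAC must be positive after the first minutes")
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    sw = np.sqrt(w)

    grid = model_grid(schedule, dt_min)
    cref_fun = _cref_interp(schedule, ref)
    cref = cref_fun(grid)

    def conv_frames(k2a):
        return frame_average(grid, expconv_uniform(cref, dt_min, k2a), schedule)

    # the R1*Cref term uses the measured frame values directly (they ARE
    # the frame-averaged reference curve); only the convolution term needs
    # the continuous reconstruction.  This keeps ROI == reference exactly
    # solvable with (R1, theta2) = (1, 0) and BP = 0 for every basis.
    best = None
    for k2a in _K2A_GRID:
        basis = conv_frames(k2a)
        A = np.column_stack([ref, basis]) * sw[:, None]
        coef, *_ = np.linalg.lstsq(A, y * sw, rcond=None)
        r1, theta2 = float(coef[0]), float(coef[1])
        k2 = theta2 + r1 * k2a
        if k2 <= 0:
            continue
        bp = k2 / k2a - 1.0
        if not (-0.95 < bp <= _BP_MAX):
            continue
        ssr = float(np.sum((A @ coef - y * sw) ** 2))
        if best is None or ssr < best[0]:
            best = (ssr, r1, k2, bp)
    if best is None:
        raise FitFailureError("no SRTM basis produced a positive k2")
    ssr, r1, k2, bp = best

    if refine:
        # polish in (R1, theta2, k2a) with k2a confined to the basis range:
        # washout rates slower than the grid floor are unresolvable within
        # the scan and collapse to a degenerate no-washout corner
        def residuals(x):
            r1_, theta2_, k2a_ = x
            return sw * (r1_ * ref + theta2_ * conv_frames(k2a_) - y)

        k2a0 = k2 / (1.0 + bp)
        try:
            res = least_squares(
                residuals,
                [r1, k2 - r1 * k2a0, k2a0],
                bounds=(
                    [0.0, -1.0, _K2A_GRID[0]],
                    [10.0, 1.0, _K2A_GRID[-1]],
                ),
            )
            r1_n, theta2_n, k2a_n = (float(v) for v in res.x)
            k2_n = theta2_n + r1_n * k2a_n
            bp_n = k2_n / k2a_n - 1.0 if k2_n > 0 else None
            # strict improvement only: along a flat ridge (e.g. ROI equal
            # to the reference) the polish must not drift from the basis
            # solution, which carries the canonical BP = 0 tie-break
            if (
                res.status > 0
                and 2.0 * res.cost < ssr * (1.0 - 1e-9)
                and bp_n is not None
                and -0.95 < bp_n <= _BP_MAX
            ):
                r1, k2, bp = r1_n, k2_n, bp_n
                ssr = float(2.0 * res.cost)
        except Exception:
            pass  # keep the basis solution
    return SRTMResult(R1=r1, k2=k2, BP=bp, gof=aic(max(ssr, 1e-300), y.size, 3))


def logan_ref(
    tac_roi: np.ndarray,
    tac_ref: np.ndarray,
    schedule: FrameSchedule,
    t_star: float = 60.0,
    k2_prime: float | None = None,
) -> LREFResult:
    """Logan reference-plot DVR from the late linear segment.

    ``k2_prime`` is the reference-region clearance rate (1/min); pass
    None to drop the Cref(T)/k2' term (late-time approximation).
    """
    y = np.asarray(tac_roi, dtype=float)
    ref = np.asarray(tac_ref, dtype=float)
    mid = frame_midtimes(schedule)
    if t_star >= mid[-1]:
        raise ValueError(f"t_star = {t_star} min lies beyond the last frame")
    sel = mid > t_star
    if np.count_nonzero(sel) < 3:
        raise ValueError("need at least 3 frames beyond t_star")
    if np.any(y[sel] <= 0):
        raise ValueError("non-positive TAC values in the Logan window")
    int_roi = cumulative_frame_integral(schedule, y)
    int_ref = cumulative_frame_integral(schedule, ref)
    num = int_ref[sel]
    if k2_prime is not None:
        if k2_prime <= 0:
            raise ValueError("k2_prime must be positive")
        num = num + ref[sel] / k2_prime
    xs = num / y[sel]
    ys = int_roi[sel] / y[sel]
    reg = linregress(xs, ys)
    return LREFResult(
        DVR=float(reg.slope),
        intercept=float(reg.intercept),
        t_star=float(t_star),
        k2_prime=k2_prime,
        n_points=int(np.count_nonzero(sel)),
        r_squared=float(reg.rvalue**2),
    )
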