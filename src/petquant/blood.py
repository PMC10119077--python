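"""Arterial blood processing: from raw samples to the corrected input function.

The measured whole-blood curve Cwb(t) is converted to a plasma curve
Cp(t) = fwb * Cwb(t) via the (time-stable) plasma-to-whole-blood ratio,
then corrected for radiometabolites with the plasma parent fraction
PPf(t) and for plasma protein binding with the free fraction fp(t):

    AIF(t) = PPf(t) * Cp(t) * fp(t)

The parent fraction is modelled with a one-exponential washout toward a
plateau,

    PPf(t) = 1 - A0 * (1 - exp(-ln(2) * t / T)),

where A0 is the asymptotic metabolite fraction and T the half-rise time
in minutes.  The free fraction is either interpolated over its sampled
time course (it need not be constant) or replaced by the mean of the
late samples.

All fractions are dimensionless in [0, 1] in memory; percent appears
only at the file boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "BloodDataset",
    "ParentFractionFit",
    "InputFunction",
    "FitFailureError",
    "ExtrapolationError",
    "estimate_fwb",
    "fit_parent_fraction",
    "eval_parent_fraction",
    "build_fp",
    "whole_blood_interpolator",
    "assemble_aif",
]

LN2 = math.log(2.0)


class FitFailureError(RuntimeError):
    """Nonlinear fit failed from every start point; carries diagnostics."""

    def __init__(self, message: str, diagnostics: list | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class ExtrapolationError(ValueError):
    """Requested grid extends too far beyond the last blood sample."""


def _check_curve(t: np.ndarray, name: str) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if t.ndim != 1:
        raise ValueError(f"{name} times must be 1-D")
    if t.size and (t.min() < 0 or not np.all(np.diff(t) > 0)):
        raise ValueError(f"{name} times must be non-negative and strictly increasing")
    return t


@dataclass
class BloodDataset:
    """Raw arterial sampling data for one subject/session.

    Times in minutes; activities in kBq/mL; fractions in [0, 1].
    ``plasma_time`` is the subset of whole-blood times with a paired
    plasma measurement.  ``fwb`` stays None until estimated.
    """

    wb_time: np.ndarray
    wb_activity: np.ndarray
    plasma_time: np.ndarray = field(default_factory=lambda: np.empty(0))
    plasma_activity: np.ndarray = field(default_factory=lambda: np.empty(0))
    ppf_time: np.ndarray = field(default_factory=lambda: np.empty(0))
    ppf_fraction: np.ndarray = field(default_factory=lambda: np.empty(0))
    fp_time: np.ndarray = field(default_factory=lambda: np.empty(0))
    fp_fraction: np.ndarray = field(default_factory=lambda: np.empty(0))
    fwb: float | None = None
    fwb_sd: float | None = None

    def __post_init__(self) -> None:
        self.wb_time = _check_curve(self.wb_time, "whole-blood")
        self.plasma_time = _check_curve(self.plasma_time, "plasma")
        self.ppf_time = _check_curve(self.ppf_time, "parent-fraction")
        self.fp_time = _check_curve(self.fp_time, "free-fraction")
        for name in ("wb_activity", "plasma_activity", "ppf_fraction", "fp_fraction"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
        if self.wb_activity.shape != self.wb_time.shape:
            raise ValueError("whole-blood times and activities differ in length")
        if self.plasma_activity.shape != self.plasma_time.shape:
            raise ValueError("plasma times and activities differ in length")
        for name in ("ppf_fraction", "fp_fraction"):
            arr = getattr(self, name)
            if arr.size and (arr.min() < 0 or arr.max() > 1):
                raise ValueError(f"{name} values must lie in [0, 1]")


@dataclass(frozen=True)
class ParentFractionFit:
    """One-exponential parent-fraction model parameters."""

    A0: float
    T: float
    ssr: float
    n: int
    t_unidentifiable: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.A0 <= 1.0):
            raise ValueError(f"A0 must lie in [0, 1], got {self.A0}")
        if not self.T > 0:
            raise ValueError(f"T must be positive, got {self.T}")


@dataclass
class InputFunction:
    """Metabolite- and free-fraction-corrected input function on a dense grid.

    Components (interpolated whole blood, plasma, PPf(t), fp(t)) are kept
    alongside the product for audit.
    """

    grid_min: np.ndarray
    aif: np.ndarray
    cwb: np.ndarray
    cp: np.ndarray
    ppf: np.ndarray
    fp: np.ndarray
    fwb: float
    fp_mode: Literal["TIME_VARYING", "LATE_MEAN"] = "TIME_VARYING"

    def __post_init__(self) -> None:
        self.grid_min = np.asarray(self.grid_min, dtype=float)
        if not np.all(np.diff(self.grid_min) > 0):
            raise ValueError("grid must be strictly increasing")
        for name in ("aif", "cwb", "cp", "ppf", "fp"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != self.grid_min.shape:
                raise ValueError(f"{name} does not match the grid length")
        if self.aif.size and self.aif.min() < 0:
            raise ValueError("AIF values must be non-negative")

    def aif_fun(self) -> Callable[[np.ndarray], np.ndarray]:
        g, v = self.grid_min, self.aif
        return lambda t: np.interp(t, g, v)

    def cwb_fun(self) -> Callable[[np.ndarray], np.ndarray]:
        g, v = self.grid_min, self.cwb
        return lambda t: np.interp(t, g, v)


def estimate_fwb(dataset: BloodDataset) -> tuple[float, float]:
    """Mean and SD of the plasma-to-whole-blood activity ratio.

    Uses the paired samples (plasma times that also carry a whole-blood
    measurement); the plasma curve is thereafter defined as fwb*Cwb(t).
    Stores the estimate on the dataset.
    """
    if dataset.plasma_time.size < 2:
        raise ValueError("need at least 2 paired plasma/whole-blood samples")
    cwb_at = np.interp(dataset.plasma_time, dataset.wb_time, dataset.wb_activity)
    if np.any(cwb_at <= 0):
        bad = dataset.plasma_time[cwb_at <= 0]
        raise ValueError(f"non-positive whole-blood activity at paired t={bad} min")
    ratios = dataset.plasma_activity / cwb_at
    mean = float(np.mean(ratios))
    sd = float(np.std(ratios, ddof=1))
    dataset.fwb, dataset.fwb_sd = mean, sd
    return mean, sd


def _ppf_model(A0: float, T: float, t: np.ndarray) -> np.ndarray:
    return 1.0 - A0 * (1.0 - np.exp(-LN2 * np.asarray(t, dtype=float) / T))


# Multi-start grid guards against local minima when the plateau is flat.
_T_STARTS = (1.0, 5.0, 10.0, 30.0, 60.0)
_A0_STARTS = (0.01, 0.05, 0.2)
_BOUNDS = ([0.0, 0.1], [1.0, 500.0])


def fit_parent_fraction(
    times_min: np.ndarray, fractions: np.ndarray
) -> ParentFractionFit:
    """Unweighted least-squares fit of the one-exponential PPf model."""
    t = np.asarray(times_min, dtype=float)
    f = np.asarray(fractions, dtype=float)
    if t.size < 3 or np.unique(t).size < 3:
        raise ValueError("need at least 3 samples at distinct times")

    def residuals(p: np.ndarray) -> np.ndarray:
        return _ppf_model(p[0], p[1], t) - f

    best = None
    diagnostics = []
    for T0 in _T_STARTS:
        for A00 in _A0_STARTS:
            try:
                res = least_squares(
                    residuals, [A00, T0], bounds=_BOUNDS,
                    ftol=1e-14, xtol=1e-14, gtol=1e-14,
                )
            except Exception as exc:  # pragma: no cover - defensive
                diagnostics.append((A00, T0, repr(exc)))
                continue
            diagnostics.append((A00, T0, res.cost, res.status))
            if res.status > 0 and (best is None or res.cost < best.cost):
                best = res
    if best is None:
        raise FitFailureError("parent-fraction fit failed from all starts", diagnostics)
    A0, T = float(best.x[0]), float(best.x[1])
    ssr = float(2.0 * best.cost)
    # With A0 at zero the curve is flat and T drops out of the model.
    unident = A0 < 1e-5
    return ParentFractionFit(A0=A0, T=T, ssr=ssr, n=t.size, t_unidentifiable=unident)


def eval_parent_fraction(fit: ParentFractionFit, t_min) -> np.ndarray | float:
    """Evaluate the fitted PPf model; value lies in [1-A0, 1]."""
    t = np.asarray(t_min, dtype=float)
    if np.any(t < 0):
        raise ValueError("parent fraction is undefined for negative times")
    out = _ppf_model(fit.A0, fit.T, t)
    return float(out) if np.isscalar(t_min) or out.ndim == 0 else out


def build_fp(
    fp_time: np.ndarray,
    fp_fraction: np.ndarray,
    mode: Literal["TIME_VARYING", "LATE_MEAN"] = "TIME_VARYING",
    late_threshold_min: float = 30.0,
) -> Callable[[np.ndarray], np.ndarray]:
    """Free plasma fraction as a function of time.

    TIME_VARYING: linear interpolation with constant extrapolation beyond
    the sampled range (the primary analysis; fp drifts over the scan).
    LATE_MEAN: constant at the mean of samples past ``late_threshold_min``
    (the simplified alternative).
    """
    t = np.asarray(fp_time, dtype=float)
    f = np.asarray(fp_fraction, dtype=float)
    if t.size < 1:
        raise ValueError("need at least one fp sample")
    if mode == "TIME_VARYING":
        if t.size < 2:
            raise ValueError("TIME_VARYING fp needs at least 2 samples")
        return lambda x: np.interp(np.asarray(x, dtype=float), t, f)
    if mode == "LATE_MEAN":
        late = f[t >= late_threshold_min]
        if late.size == 0:
            raise ValueError(
                f"no fp samples at t >= {late_threshold_min} min for LATE_MEAN"
            )
        const = float(np.mean(late))
        return lambda x: np.full_like(np.asarray(x, dtype=float), const)
    raise ValueError(f"unknown fp mode {mode!r}")


def whole_blood_interpolator(
    dataset: BloodDataset, tail_points: int = 3
) -> Callable[[np.ndarray], np.ndarray]:
    """Continuous whole-blood curve from discrete samples.

    Linear rise from (0, 0) to the first sample, piecewise-linear through
    the samples, and a single-exponential tail fitted to the final
    ``tail_points`` samples for times past the last draw.
    """
    t = dataset.wb_time
    c = dataset.wb_activity
    if t.size < 2:
        raise ValueError("need at least 2 whole-blood samples")
    if t[0] > 0:
        t_nodes = np.concatenate([[0.0], t])
        c_nodes = np.concatenate([[0.0], c])
    else:
        t_nodes, c_nodes = t, c

    # exponential tail: log-linear LSQ on the last positive samples
    tt, cc = t[-tail_points:], c[-tail_points:]
    if np.all(cc > 0) and tt.size >= 2:
        slope, intercept = np.polyfit(tt, np.log(cc), 1)
        lam_tail = max(-slope, 0.0)
        c_last = float(cc[-1])
        t_last = float(tt[-1])
    else:  # degenerate: hold the last value
        lam_tail, c_last, t_last = 0.0, float(c[-1]), float(t[-1])

    def fun(x):
        x = np.asarray(x, dtype=float)
        out = np.interp(x, t_nodes, c_nodes)
        beyond = x > t_last
        if np.any(beyond):
            out = np.where(beyond, c_last * np.exp(-lam_tail * (x - t_last)), out)
        return out

    return fun


def assemble_aif(
    dataset: BloodDataset,
    ppf_fit: ParentFractionFit,
    fp_fun: Callable[[np.ndarray], np.ndarray],
    grid_min: np.ndarray,
    fp_mode: Literal["TIME_VARYING", "LATE_MEAN"] = "TIME_VARYING",
    extrapolation_margin_min: float = 30.0,
) -> InputFunction:
    """Assemble AIF(t) = PPf(t) * fwb * Cwb(t) * fp(t) on a dense grid."""
    if dataset.fwb is None:
        raise ValueError("fwb has not been estimated; call estimate_fwb first")
    grid = np.asarray(grid_min, dtype=float)
    last_sample = float(dataset.wb_time[-1])
    if grid[-1] > last_sample + extrapolation_margin_min:
        raise ExtrapolationError(
            f"grid end {grid[-1]:.1f} min exceeds last blood sample "
            f"{last_sample:.1f} min by more than {extrapolation_margin_min:.0f} min"
        )
    cwb = whole_blood_interpolator(dataset)(grid)
    ppf = np.asarray(eval_parent_fraction(ppf_fit, grid))
    fp = np.asarray(fp_fun(grid), dtype=float)
    cp = dataset.fwb * cwb
    aif = np.clip(ppf * cp * fp, 0.0, None)
    return InputFunction(
        grid_min=grid, aif=aif, cwb=cwb, cp=cp, ppf=ppf, fp=fp,
        fwb=dataset.fwb, fp_mode=fp_mode,
    )
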