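"""Fluorescence-trace preprocessing: ROI averaging, photobleaching
correction, box-car smoothing, and ΔF/F extraction.

The processing chain mirrors standard voltage/calcium-imaging practice:
the per-frame mean over a region of interest is fit with a
two-exponential-plus-offset bleaching baseline (the stimulus window is
excluded from the fit by default so responses do not bias it), the
baseline is divided out, the corrected trace is smoothed by repeated
box-car (moving-average) passes, and ΔF/F is reported in percent
relative to a pre-stimulus baseline window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.optimize import least_squares

from .core import (
    BleachModel,
    FitFailureError,
    InvalidInputError,
    InvalidParameterError,
    TimeSeries,
)

__all__ = ["DFFTrace", "roi_average", "fit_bleach", "detrend", "boxcar", "dff", "process_trace"]


@dataclass
class DFFTrace(TimeSeries):
    """ΔF/F trace in percent, with its baseline window and processing
    provenance (bleach parameters, smoothing width/rounds, mode)."""

    baseline_window: tuple[float, float] = (0.0, 0.0)
    bleach: BleachModel | None = None
    smooth_width: int = 1
    smooth_rounds: int = 0
    mode: str = "divide"


def roi_average(stack: np.ndarray, mask: np.ndarray, sample_rate: float, t0: float = 0.0) -> TimeSeries:
    """Per-frame unweighted mean intensity over the masked pixels."""
    stack = np.asarray(stack, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if stack.ndim != 3:
        raise InvalidInputError("stack must be 3-D (frames, rows, cols)")
    if mask.shape != stack.shape[1:]:
        raise InvalidInputError(f"mask shape {mask.shape} != frame shape {stack.shape[1:]}")
    if not mask.any():
        raise InvalidInputError("mask must contain at least one pixel")
    return TimeSeries(t0=t0, sample_rate=sample_rate, values=stack[:, mask].mean(axis=1))


def _bleach_curve(t, a_fast, a_slow, tau_fast, tau_slow, offset):
    return a_fast * np.exp(-t / tau_fast) + a_slow * np.exp(-t / tau_slow) + offset


def _linear_amplitudes(t, y, tau_fast, tau_slow):
    """For fixed taus the model is linear in (a_fast, a_slow, offset)."""
    A = np.column_stack([np.exp(-t / tau_fast), np.exp(-t / tau_slow), np.ones_like(t)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return coef, float(resid @ resid)


def fit_bleach(trace: TimeSeries, exclude_window: tuple[float, float] | None = None) -> BleachModel:
    """Least-squares two-exponential-plus-offset fit of the bleaching
    baseline, ignoring samples inside ``exclude_window`` (typically the
    stimulus/response window).

    Multi-start: candidate (tau_fast, tau_slow) pairs span several decades
    of the trace duration; for each pair the amplitudes and offset are
    solved linearly (variable projection), and the best candidate is
    refined by bounded nonlinear least squares.
    """
    t_all, y_all = trace.times, trace.values
    if exclude_window is not None:
        lo, hi = exclude_window
        keep = (t_all < lo) | (t_all >= hi)
    else:
        keep = np.ones(t_all.size, dtype=bool)
    t, y = t_all[keep], y_all[keep]
    if t.size < 10:
        raise InvalidInputError("need at least 10 samples outside the excluded window")

    span = max(t[-1] - t[0], 10 * trace.dt)
    taus = np.geomspace(span / 300.0, span * 3.0, 8)
    best = None
    for i, tf in enumerate(taus):
        for ts_ in taus[i + 1 :]:
            coef, sse = _linear_amplitudes(t, y, tf, ts_)
            if best is None or sse < best[0]:
                best = (sse, tf, ts_, coef)
    _, tf0, ts0, (af0, as0, off0) = best

    def resid(p):
        return _bleach_curve(t, *p) - y

    scale = max(float(np.abs(y).max()), 1.0)
    try:
        sol = least_squares(
            resid,
            x0=[af0, as0, tf0, ts0, off0],
            bounds=([-np.inf, -np.inf, span / 1e4, span / 1e4, -np.inf],
                    [np.inf, np.inf, span * 1e3, span * 1e3, np.inf]),
            xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=20_000,
        )
    except Exception as exc:  # pragma: no cover - defensive
        raise FitFailureError("bleach fit raised", {"error": str(exc)}) from exc
    if not sol.success and np.sqrt(sol.cost) > 1e-3 * scale * np.sqrt(t.size):
        raise FitFailureError(
            "bleach fit did not converge",
            {"status": sol.status, "cost": float(sol.cost), "x": sol.x.tolist()},
        )
    af, as_, tf, ts_, off = sol.x
    return BleachModel(a_fast=af, a_slow=as_, tau_fast_s=tf, tau_slow_s=ts_, offset=off)


def detrend(trace: TimeSeries, model: BleachModel, mode: str = "divide") -> TimeSeries:
    """Remove the fitted bleach baseline.

    divide:   trace / b(t)           (multiplicative bleach; default)
    subtract: trace − b(t) + offset  (additive bleach)
    """
    b = model.baseline(trace.times)
    if mode == "divide":
        if np.any(b <= 0):
            raise InvalidInputError("baseline must be positive for divide-mode detrending")
        return trace.copy_with(trace.values / b)
    if mode == "subtract":
        return trace.copy_with(trace.values - b + model.offset)
    raise InvalidParameterError(f"unknown detrend mode {mode!r}")


def boxcar(trace: TimeSeries, width: int = 3, rounds: int = 8) -> TimeSeries:
    """``rounds`` successive centered moving averages of odd ``width``.

    Edges are handled by reflection so repeated passes do not droop at
    the endpoints.  width=1 is the identity.
    """
    if width < 1 or width % 2 == 0:
        raise InvalidParameterError("width must be odd and >= 1")
    if rounds < 0:
        raise InvalidParameterError("rounds must be >= 0")
    v = trace.values
    for _ in range(rounds if width > 1 else 0):
        v = uniform_filter1d(v, size=width, mode="reflect")
    return trace.copy_with(v)


def dff(trace: TimeSeries, baseline_window: tuple[float, float]) -> DFFTrace:
    """Percent ΔF/F: 100·(F − F0)/F0 with F0 the mean over the (pre-
    stimulus) baseline window."""
    f0 = float(np.mean(trace.window_slice(*baseline_window)))
    if f0 <= 0:
        raise InvalidInputError(f"baseline mean F0 must be positive, got {f0}")
    return DFFTrace(
        t0=trace.t0,
        sample_rate=trace.sample_rate,
        values=100.0 * (trace.values - f0) / f0,
        baseline_window=baseline_window,
    )


def process_trace(
    trace: TimeSeries,
    baseline_window: tuple[float, float],
    exclude_window: tuple[float, float] | None = None,
    width: int = 3,
    rounds: int = 8,
    mode: str = "divide",
    invert: bool = False,
) -> DFFTrace:
    """Full chain: bleach fit → detrend → box-car smoothing → % ΔF/F.

    ``invert=True`` flips the sign of the result, the loading convention
    for voltage indicators that dim on depolarization, so processed
    responses are positive-going.
    """
    model = fit_bleach(trace, exclude_window=exclude_window)
    corrected = detrend(trace, model, mode=mode)
    smoothed = boxcar(corrected, width=width, rounds=rounds)
    out = dff(smoothed, baseline_window)
    if invert:
        out.values = -out.values
    out.bleach = model
    out.smooth_width = width
    out.smooth_rounds = rounds
    out.mode = mode
    return out
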