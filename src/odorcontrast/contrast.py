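"""Temporal-contrast statistics.

The sharpness coefficient quantifies how completely neuronal activity
returns toward baseline after an odor pulse:

    sharpness = (reference − post) / reference

where ``post`` is the activity 1.5 s after odor offset and ``reference``
is either the in-pulse maximum (the *max* variant) or the activity at the
moment of odor offset (the *offset* variant, which discounts sensory
adaptation).  A coefficient of 1 means 100 % temporal contrast (activity
fully back at baseline); 0 means none.  Negative coefficients occur when
the postpulse value exceeds the reference (rebound) and are reported,
never clamped.

``decay_time`` is the stimulus-decay statistic: the time a trace takes to
fall from its peak to 36.8 % (e⁻¹) of the peak value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import TimeSeries, UndefinedResultError

__all__ = [
    "SharpnessResult",
    "sharpness_max",
    "sharpness_offset",
    "sharpness_timecourse",
    "decay_time",
]

POSTPULSE_DELAY_S = 1.5
DECAY_FRACTION = np.exp(-1.0)  # 0.368 of peak


@dataclass
class SharpnessResult:
    """One sharpness evaluation: the variant used, the reference and
    postpulse values (signal units), the postpulse delay, and the
    dimensionless coefficient."""

    variant: str
    reference_value: float
    post_value: float
    delay_s: float
    coefficient: float


def _post_value(trace: TimeSeries, offset_time: float, delay_s: float, window_s: float) -> float:
    """Postpulse sample: nearest-sample point value by default, or the
    mean over a small centered window if ``window_s`` > 0."""
    if window_s <= 0:
        return trace.value_at(offset_time + delay_s)
    t = offset_time + delay_s
    return float(np.mean(trace.window_slice(t - window_s / 2, t + window_s / 2)))


def sharpness_max(
    trace: TimeSeries,
    offset_time: float,
    delay_s: float = POSTPULSE_DELAY_S,
    onset_time: float | None = None,
    post_window_s: float = 0.0,
) -> SharpnessResult:
    """Peak-referenced sharpness: (max − post)/max.

    The reference is the trace maximum over the stimulus window
    [onset_time, offset_time] (the whole trace up to offset if
    ``onset_time`` is None); ``post`` is the value ``delay_s`` after
    offset (nearest sample).
    """
    start = trace.t0 if onset_time is None else onset_time
    ref = float(np.max(trace.window_slice(start, offset_time + trace.dt / 2)))
    if ref == 0:
        raise UndefinedResultError("sharpness_max undefined: in-pulse maximum is zero")
    post = _post_value(trace, offset_time, delay_s, post_window_s)
    return SharpnessResult(
        variant="max",
        reference_value=ref,
        post_value=post,
        delay_s=delay_s,
        coefficient=(ref - post) / ref,
    )


def sharpness_offset(
    trace: TimeSeries,
    offset_time: float,
    delay_s: float = POSTPULSE_DELAY_S,
    post_window_s: float = 0.0,
) -> SharpnessResult:
    """Offset-referenced sharpness: (value@offset − post)/value@offset.

    Using the activity at odor offset as the reference discounts sensory
    adaptation during the pulse, isolating how fast activity falls after
    the stimulus ends.
    """
    ref = trace.value_at(offset_time)
    if ref == 0:
        raise UndefinedResultError("sharpness_offset undefined: value at offset is zero")
    post = _post_value(trace, offset_time, delay_s, post_window_s)
    return SharpnessResult(
        variant="offset",
        reference_value=ref,
        post_value=post,
        delay_s=delay_s,
        coefficient=(ref - post) / ref,
    )


def sharpness_timecourse(
    trace: TimeSeries, offset_time: float, delays: np.ndarray
) -> TimeSeries:
    """Offset-referenced sharpness as a function of postpulse delay.

    Element ``d`` of the result equals
    ``sharpness_offset(trace, offset_time, d).coefficient``; the delay
    grid must be uniform (it becomes the time axis of the returned
    series).
    """
    delays = np.asarray(delays, dtype=float)
    coeffs = np.array(
        [sharpness_offset(trace, offset_time, d).coefficient for d in delays]
    )
    step = delays[1] - delays[0] if delays.size > 1 else 1.0
    return TimeSeries(t0=float(delays[0]), sample_rate=1.0 / step, values=coeffs)


def decay_time(trace: TimeSeries, threshold_frac: float = DECAY_FRACTION) -> float | None:
    """Time from the trace peak to ``threshold_frac`` (default e⁻¹ ≈
    36.8 %) of the peak value, with linear interpolation between the
    straddling samples.

    Returns None when the trace never falls to the threshold after its
    peak (e.g. a monotonically increasing trace).
    """
    v = trace.values
    i_peak = int(np.argmax(v))  # first maximum on ties
    peak = v[i_peak]
    target = threshold_frac * peak
    below = np.flatnonzero(v[i_peak:] <= target)
    if below.size == 0:
        return None
    j = i_peak + below[0]
    t = trace.times
    if j == i_peak or v[j] == target or v[j - 1] == v[j]:
        t_cross = t[j]
    else:
        frac = (v[j - 1] - target) / (v[j - 1] - v[j])
        t_cross = t[j - 1] + frac * (t[j] - t[j - 1])
    return float(t_cross - t[i_peak])
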