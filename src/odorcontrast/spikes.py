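"""Extracellular sensillum-recording analysis.

Raw 10 kHz voltage traces are zero-phase band-pass filtered (300 Hz to
2 kHz), spikes are detected with a robust MAD-based amplitude threshold,
sorted into amplitude classes by one-dimensional 2-means (the larger-
amplitude class is labelled "A"), and converted to sliding-window firing
rates.  ``postpulse_comparison`` implements the spontaneous-versus-
postpulse firing comparison sampled 1.5 s after odor-pulse offset.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .core import InvalidInputError, InvalidParameterError, SpikeTrain, TimeSeries
from .synthgen import OdorPulseSpec

__all__ = [
    "bandpass",
    "detect_spikes",
    "sort_units",
    "firing_rate",
    "postpulse_comparison",
]


def bandpass(raw: TimeSeries, lo: float = 300.0, hi: float = 2000.0, order: int = 3) -> TimeSeries:
    """Zero-phase Butterworth band-pass; removes DC and line-frequency
    drift while passing the ~1 kHz spike band."""
    nyq = raw.sample_rate / 2.0
    if not 0 < lo < hi < nyq:
        raise InvalidParameterError(
            f"band ({lo}, {hi}) Hz must lie inside (0, Nyquist={nyq}) Hz"
        )
    sos = butter(order, [lo, hi], btype="bandpass", fs=raw.sample_rate, output="sos")
    return raw.copy_with(sosfiltfilt(sos, raw.values))


def detect_spikes(
    filtered: TimeSeries, k_mad: float = 5.0, refractory_ms: float = 2.0
) -> pd.DataFrame:
    """Threshold crossings of ``k_mad`` × the MAD-estimated noise SD.

    The spike time is the local absolute extremum within ±1 ms of the
    crossing and the amplitude is the signed trace value there; events
    closer than the refractory period to an accepted event are dropped
    (earliest-first).  Returns a DataFrame with ``time_s`` and
    ``amplitude`` columns, sorted by time.
    """
    v = filtered.values
    sr = filtered.sample_rate
    mad = np.median(np.abs(v - np.median(v)))
    thresh = k_mad * mad / 0.6745  # MAD → SD for Gaussian noise
    empty = pd.DataFrame({"time_s": pd.Series(dtype=float), "amplitude": pd.Series(dtype=float)})
    if thresh == 0 or not np.any(np.abs(v) > thresh):
        return empty

    above = np.abs(v) > thresh
    crossings = np.flatnonzero(above & ~np.roll(above, 1))
    crossings = crossings[crossings > 0]  # roll wraps index 0
    if above[0]:
        crossings = np.insert(crossings, 0, 0)

    half = max(1, int(round(1e-3 * sr)))  # ±1 ms extremum search
    refr = int(round(refractory_ms * 1e-3 * sr))
    cand: dict[int, float] = {}
    for c in crossings:
        lo_i, hi_i = max(0, c - half), min(v.size, c + half + 1)
        ext = lo_i + int(np.argmax(np.abs(v[lo_i:hi_i])))
        cand[ext] = v[ext]
    # refractory suppression keeps the largest event in each conflict
    # (zero-phase filtering pre-rings, so the first crossing can sit on a
    # side lobe just before the true peak)
    order = sorted(cand, key=lambda i: (-abs(cand[i]), i))
    accepted: list[int] = []
    for i in order:
        if all(abs(i - j) >= refr for j in accepted):
            accepted.append(i)
    accepted.sort()
    out = pd.DataFrame(
        {"time_s": [filtered.t0 + i / sr for i in accepted],
         "amplitude": [cand[i] for i in accepted]}
    )
    return out.reset_index(drop=True)


def sort_units(events: pd.DataFrame, n_units: int = 2) -> list[SpikeTrain]:
    """Amplitude-based unit sorting by deterministic 1-D k-means.

    Cluster centers are initialized at evenly spaced quantiles of the
    absolute amplitude distribution (25th/75th percentile for two units),
    so the result is independent of event order.  The larger-amplitude
    cluster is labelled "A", the next "B", and so on.  With fewer events
    than units, or with zero amplitude spread, all events fall back to a
    single unit and a warning is emitted.
    """
    if events.empty:
        return []
    amp = np.abs(events["amplitude"].to_numpy(float))
    t = events["time_s"].to_numpy(float)
    order = np.argsort(t)
    amp, t = amp[order], t[order]
    signed = events["amplitude"].to_numpy(float)[order]

    if len(events) < n_units or np.ptp(amp) == 0:
        warnings.warn("too few events or no amplitude spread; returning a single unit")
        return [SpikeTrain(unit_label="A", times=t, amplitudes=signed)]

    qs = (np.arange(n_units) + 1.0) / (n_units + 1.0)  # e.g. 0.25, 0.75
    centers = np.quantile(amp, qs)
    for _ in range(200):
        labels = np.argmin(np.abs(amp[:, None] - centers[None, :]), axis=1)
        new = np.array(
            [amp[labels == j].mean() if np.any(labels == j) else centers[j] for j in range(n_units)]
        )
        if np.allclose(new, centers):
            break
        centers = new

    # rank clusters by mean amplitude, largest first → "A", "B", ...
    rank = np.argsort(-centers)
    trains = []
    for pos, j in enumerate(rank):
        sel = labels == j
        if not sel.any():
            continue
        trains.append(
            SpikeTrain(unit_label=chr(ord("A") + pos), times=t[sel], amplitudes=signed[sel])
        )
    return trains


def firing_rate(
    train: SpikeTrain,
    window_s: float = 0.1,
    step_s: float = 0.008,
    t_start: float = 0.0,
    t_stop: float | None = None,
    kernel: str = "rect",
) -> TimeSeries:
    """Sliding-window firing-rate estimate on a uniform grid.

    rect (default): spike count in a centered rectangular window divided
    by ``window_s``.  gauss: Gaussian kernel with SD ``window_s``/2
    (normalized to unit area), a smoother alternative.
    """
    if window_s <= 0 or step_s <= 0:
        raise InvalidParameterError("window_s and step_s must be positive")
    if t_stop is None:
        t_stop = float(train.times[-1]) + window_s if train.n else t_start + window_s
    grid = np.arange(t_start, t_stop + step_s / 2, step_s)
    if train.n == 0:
        return TimeSeries(t0=t_start, sample_rate=1.0 / step_s, values=np.zeros(grid.size))
    if kernel == "rect":
        half = window_s / 2.0
        counts = np.searchsorted(train.times, grid + half) - np.searchsorted(
            train.times, grid - half
        )
        rate = counts / window_s
    elif kernel == "gauss":
        sd = window_s / 2.0
        diffs = grid[:, None] - train.times[None, :]
        rate = np.exp(-0.5 * (diffs / sd) ** 2).sum(axis=1) / (sd * np.sqrt(2 * np.pi))
    else:
        raise InvalidParameterError(f"unknown kernel {kernel!r}")
    return TimeSeries(t0=t_start, sample_rate=1.0 / step_s, values=rate.astype(float))


def postpulse_comparison(
    rate: TimeSeries,
    pulse: OdorPulseSpec,
    delay_s: float = 1.5,
    spont_window: tuple[float, float] | None = None,
) -> dict:
    """Spontaneous versus postpulse firing rate.

    ``spont_hz`` is the mean rate over the pre-stimulus window (defaults
    to everything before odor onset); ``post_hz`` is the rate sampled
    ``delay_s`` after odor-pulse offset.
    """
    if spont_window is None:
        spont_window = (rate.t0, pulse.onset_s)
    spont = float(np.mean(rate.window_slice(*spont_window)))
    post = rate.value_at(pulse.offset_s + delay_s)
    return {"spont_hz": spont, "post_hz": post}
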