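"""Synthetic recordings with the statistical structure the analysis assumes.

This module generates every input the quantification chain consumes, so the
whole pipeline is testable without lab data:

* PID odor-pulse waveforms (first-order rise/decay), including the
  distance-dependent broadening seen inside a closed walking arena;
* OSN firing-rate traces with adaptation, threshold-gated sustained
  postpulse activity, and poststimulus inhibition;
* presynaptic inhibition by fast (GABA_A-like) and slow (GABA_B-like)
  rate-driven exponential kernels;
* Poisson spike trains, 10 kHz extracellular voltage, voltage-indicator
  (125 Hz) and calcium-indicator (40 Hz) fluorescence on a two-exponential
  bleach baseline, 80×80 movies;
* trajectories of walking flies in a 10 cm circular arena with
  concentration-dependent drift toward or away from the active odor port.

All stochastic generators take an integer seed and are deterministic for a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .core import (
    ArenaConfig,
    BleachModel,
    InvalidInputError,
    InvalidParameterError,
    SpikeTrain,
    TimeSeries,
    Trajectory,
)

__all__ = [
    "OdorPulseSpec",
    "OSNParams",
    "InhibitionParams",
    "BehaviorParams",
    "make_odor_pulse",
    "default_arena_profile",
    "arena_pid",
    "osn_rate",
    "apply_presynaptic_inhibition",
    "sample_spikes",
    "render_extracellular",
    "render_arclight",
    "render_gcamp",
    "render_movie",
    "simulate_flies",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class OdorPulseSpec:
    """A single valve-controlled odor pulse as seen by a PID.

    ``peak`` is the asymptotic PID amplitude (a.u.); the waveform rises
    toward it with ``rise_tau_s`` during the pulse and decays with
    ``decay_tau_s`` after valve closure.
    """

    onset_s: float = 1.0
    duration_s: float = 1.0
    peak: float = 1.0
    rise_tau_s: float = 0.05
    decay_tau_s: float = 0.1
    dilution_label: str = "1:5"

    def __post_init__(self) -> None:
        if self.duration_s < 0:
            raise InvalidParameterError("duration_s must be >= 0")
        if self.peak <= 0:
            raise InvalidParameterError("peak must be > 0")
        if self.rise_tau_s <= 0 or self.decay_tau_s <= 0:
            raise InvalidParameterError("rise/decay time constants must be > 0")

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class OSNParams:
    """Phenomenological OSN rate model.

    r(t) = clamp≥0[ r_spont + gain·a(t)·c(t) + S(t) − I(t) ]

    * a(t): multiplicative adaptation, relaxing from 1 toward
      (1 − adapt_depth) with time constant ``adapt_tau_s`` while the
      stimulus is on, and recovering toward 1 when it is off.
    * S(t): sustained postpulse component, charged only while the
      concentration is at or above ``sustain_threshold`` (amplitude
      ``sustain_gain``·(c − threshold)) and decaying with
      ``sustain_decay_s`` afterwards.  This models the sustained firing
      seen only at high odor intensities.
    * I(t): poststimulus inhibition of depth ``inhib_depth`` triggered at
      stimulus offset when no sustained component was charged, decaying
      with ``inhib_tau_s``.
    """

    r_spont: float = 8.0
    gain: float = 150.0
    adapt_tau_s: float = 0.35
    adapt_depth: float = 0.5
    sustain_threshold: float = 0.5
    sustain_gain: float = 60.0
    sustain_decay_s: float = 2.5
    inhib_depth: float = 6.0
    inhib_tau_s: float = 0.8

    def __post_init__(self) -> None:
        if self.r_spont < 0 or self.inhib_depth < 0:
            raise InvalidParameterError("r_spont and inhib_depth must be >= 0")
        if not 0 <= self.adapt_depth <= 1:
            raise InvalidParameterError("adapt_depth must lie in [0, 1]")
        if self.adapt_tau_s <= 0 or self.sustain_decay_s <= 0 or self.inhib_tau_s <= 0:
            raise InvalidParameterError("time constants must be > 0")


@dataclass
class InhibitionParams:
    """Presynaptic inhibition by two rate-driven exponential kernels.

    The fast kernel stands for ionotropic (GABA_A-like) inhibition, the
    slow one for metabotropic (GABA_B-like) inhibition; each can be
    toggled to emulate pharmacology or receptor knockdown.
    """

    gA_weight: float = 0.2
    gA_tau_s: float = 0.08
    gB_weight: float = 0.35
    gB_tau_s: float = 1.2
    gA_enabled: bool = True
    gB_enabled: bool = True

    def __post_init__(self) -> None:
        if self.gA_weight < 0 or self.gB_weight < 0:
            raise InvalidParameterError("kernel weights must be >= 0")
        if not 0 < self.gA_tau_s < self.gB_tau_s:
            raise InvalidParameterError("need 0 < gA_tau_s < gB_tau_s (fast < slow)")


@dataclass
class BehaviorParams:
    """Random-walk-with-drift model of a walking fly.

    ``drift_gain`` maps local odor concentration to a signed radial drift
    speed (cm/s): positive values drive the fly toward the port
    (attraction), negative away (avoidance).  The drift acts on the
    concentration sensed ``sensing_latency_s`` ago and, once engaged,
    persists for ``persistence_s`` after the local concentration declines.
    """

    base_speed: float = 1.0
    heading_diffusion: float = 2.0
    drift_gain: Callable[[float], float] = field(default=lambda c: 0.0)
    persistence_s: float = 0.0
    sensing_latency_s: float = 0.1

    def __post_init__(self) -> None:
        if self.base_speed < 0 or self.persistence_s < 0 or self.sensing_latency_s < 0:
            raise InvalidParameterError(
                "base_speed, persistence_s and sensing_latency_s must be >= 0"
            )


def avoidance_drift(gain: float = 1.2, c_mid: float = 0.15) -> Callable[[float], float]:
    """Saturating avoidance drive: −gain·c/(c + c_mid) cm/s."""
    return lambda c: -gain * c / (c + c_mid)


def attraction_drift(gain: float = 0.8, c_mid: float = 0.05) -> Callable[[float], float]:
    """Saturating attraction drive: +gain·c/(c + c_mid) cm/s."""
    return lambda c: gain * c / (c + c_mid)


# ---------------------------------------------------------------------------
# odor pulses
# ---------------------------------------------------------------------------

def make_odor_pulse(spec: OdorPulseSpec, total_s: float, sample_rate: float) -> TimeSeries:
    """Noiseless PID trace of a single valve-controlled pulse.

    Zero before onset; first-order rise toward ``spec.peak`` during the
    pulse; first-order decay from the value reached at valve closure.
    """
    if sample_rate <= 0:
        raise InvalidParameterError("sample_rate must be > 0")
    if total_s < spec.offset_s:
        raise InvalidParameterError(
            f"total_s={total_s} does not cover the pulse (offset at {spec.offset_s} s)"
        )
    n = int(round(total_s * sample_rate))
    t = np.arange(n) / sample_rate
    c = np.zeros(n)
    if spec.duration_s > 0:
        on = (t >= spec.onset_s) & (t < spec.offset_s)
        c[on] = spec.peak * (1.0 - np.exp(-(t[on] - spec.onset_s) / spec.rise_tau_s))
        c_off = spec.peak * (1.0 - np.exp(-spec.duration_s / spec.rise_tau_s))
        post = t >= spec.offset_s
        c[post] = c_off * np.exp(-(t[post] - spec.offset_s) / spec.decay_tau_s)
    return TimeSeries(t0=0.0, sample_rate=sample_rate, values=c)


def default_arena_profile(distance_cm: float) -> tuple[float, float]:
    """Distance dependence of the pulse shape inside the closed arena.

    Returns ``(peak_scale, tau_scale)`` multipliers.  The peak falls off
    smoothly with distance, while the decay time constant increases
    steeply beyond 3–4 cm from the port — close to the port the fly sees
    plume-like entry/exit dynamics, farther away only a slow swell.
    """
    if distance_cm < 0:
        raise InvalidParameterError("distance must be >= 0")
    peak_scale = float(np.exp(-distance_cm / 4.0))
    # logistic step centred at 3.5 cm: tau ~×1 near the port, ~×10 beyond
    tau_scale = float(1.0 + 9.0 / (1.0 + np.exp(-(distance_cm - 3.5) / 0.35)))
    return peak_scale, tau_scale


def arena_pid(
    distance_cm: float,
    spec: OdorPulseSpec,
    profile: Callable[[float], tuple[float, float]] = default_arena_profile,
    total_s: float | None = None,
    sample_rate: float = 125.0,
    arena_diameter_cm: float = 10.0,
) -> TimeSeries:
    """PID waveform at a given distance from the odor port.

    ``profile(distance) -> (peak_scale, tau_scale)`` rescales the pulse
    peak (non-increasing with distance) and decay time constant
    (non-decreasing, with a steep increase beyond 3–4 cm).
    """
    if distance_cm < 0:
        raise InvalidParameterError("distance must be >= 0")
    if distance_cm > arena_diameter_cm:
        raise InvalidParameterError(
            f"distance {distance_cm} cm exceeds the arena diameter {arena_diameter_cm} cm"
        )
    peak_scale, tau_scale = profile(distance_cm)
    local = OdorPulseSpec(
        onset_s=spec.onset_s,
        duration_s=spec.duration_s,
        peak=spec.peak * peak_scale,
        rise_tau_s=spec.rise_tau_s,
        decay_tau_s=spec.decay_tau_s * tau_scale,
        dilution_label=spec.dilution_label,
    )
    if total_s is None:
        total_s = spec.offset_s + 8.0 * local.decay_tau_s + 1.0
    return make_odor_pulse(local, total_s=total_s, sample_rate=sample_rate)


# ---------------------------------------------------------------------------
# OSN firing rate
# ---------------------------------------------------------------------------

def osn_rate(pid: TimeSeries, p: OSNParams) -> TimeSeries:
    """Instantaneous OSN firing rate driven by a PID concentration trace.

    Integrates the adaptation / sustained-activity / poststimulus-
    inhibition model (see :class:`OSNParams`) sample by sample on the PID
    time grid.
    """
    c = pid.values
    if np.any(c < 0):
        raise InvalidInputError("pid concentrations must be nonnegative")
    dt = pid.dt
    n = pid.n
    eps = 1e-3 * max(c.max(), 1.0) if c.max() > 0 else 1e-12

    a = 1.0
    S = 0.0
    inhib = 0.0
    running_max = 0.0
    inhib_armed = False
    r = np.empty(n)
    ad_decay = np.exp(-dt / p.adapt_tau_s)
    s_decay = np.exp(-dt / p.sustain_decay_s)
    i_decay = np.exp(-dt / p.inhib_tau_s)
    for i in range(n):
        ci = c[i]
        stimulated = ci > eps
        target = (1.0 - p.adapt_depth) if stimulated else 1.0
        a = target + (a - target) * ad_decay

        s_target = p.sustain_gain * max(0.0, ci - p.sustain_threshold)
        S = max(s_target, S * s_decay)

        if stimulated:
            running_max = max(running_max, ci)
            inhib_armed = True
        inhib *= i_decay
        if inhib_armed and running_max > 0 and ci < 0.05 * running_max:
            # stimulus offset: trigger inhibition once, only if no
            # sustained component was charged during the pulse
            if S < 1e-9:
                inhib = p.inhib_depth
            inhib_armed = False
            running_max = 0.0

        r[i] = max(0.0, p.r_spont + p.gain * a * ci + S - inhib)
    return pid.copy_with(r)


# ---------------------------------------------------------------------------
# presynaptic inhibition
# ---------------------------------------------------------------------------

def _causal_exp_kernel(tau_s: float, dt: float, support_taus: float = 8.0) -> np.ndarray:
    """Unit-area causal exponential kernel sampled at dt."""
    n = max(2, int(round(support_taus * tau_s / dt)))
    k = np.exp(-np.arange(n) * dt / tau_s)
    return k / (k.sum() * dt)


def apply_presynaptic_inhibition(rate: TimeSeries, q: InhibitionParams) -> TimeSeries:
    """Subtract fast and slow rate-driven inhibition from a rate trace.

    i(t) = gA_weight·(k_A ∗ rate)(t)·[gA on] + gB_weight·(k_B ∗ rate)(t)·[gB on]
    with unit-area causal exponential kernels; output = clamp≥0(rate − i).
    The slow kernel keeps subtracting after the pulse, which is what
    truncates sustained postpulse activity and sharpens the response.
    """
    if np.any(rate.values < 0):
        raise InvalidInputError("rate must be nonnegative")
    dt = rate.dt
    i_total = np.zeros(rate.n)
    for weight, tau, enabled in (
        (q.gA_weight, q.gA_tau_s, q.gA_enabled),
        (q.gB_weight, q.gB_tau_s, q.gB_enabled),
    ):
        if not enabled or weight == 0:
            continue
        k = _causal_exp_kernel(tau, dt)
        i_total += weight * np.convolve(rate.values, k)[: rate.n] * dt
    return rate.copy_with(np.maximum(0.0, rate.values - i_total))


# ---------------------------------------------------------------------------
# spikes and extracellular voltage
# ---------------------------------------------------------------------------

def sample_spikes(rate: TimeSeries, refractory_s: float = 0.002, seed: int = 0) -> SpikeTrain:
    """Inhomogeneous Poisson spike train with absolute refractoriness.

    Thinning: homogeneous candidates at the rate ceiling are accepted with
    probability r(t)/r_max; candidates within ``refractory_s`` of the last
    accepted spike are discarded.  Deterministic for a fixed seed.
    """
    if np.any(rate.values < 0):
        raise InvalidInputError("rate must be nonnegative")
    rng = np.random.default_rng(seed)
    r_max = float(rate.values.max())
    if r_max == 0:
        return SpikeTrain(unit_label="A", times=np.empty(0), amplitudes=np.empty(0))
    t_end = rate.t0 + rate.duration
    # homogeneous candidate times
    n_cand = rng.poisson(r_max * rate.duration)
    cand = np.sort(rng.uniform(rate.t0, t_end, size=n_cand))
    u = rng.uniform(size=n_cand)
    times = []
    last = -np.inf
    for tc, uc in zip(cand, u):
        if tc - last < refractory_s:
            continue
        idx = min(rate.n - 1, int((tc - rate.t0) * rate.sample_rate))
        if uc < rate.values[idx] / r_max:
            times.append(tc)
            last = tc
    times = np.asarray(times)
    return SpikeTrain(unit_label="A", times=times, amplitudes=np.ones(times.size))


def _biphasic_template(sample_rate: float, width_s: float = 0.002) -> np.ndarray:
    """Fixed biphasic spike waveform of ~2 ms support, peak amplitude 1."""
    n = max(3, int(round(width_s * sample_rate)))
    u = np.arange(n) / n
    w = np.sin(2 * np.pi * u) * np.sin(np.pi * u)  # biphasic, tapered ends
    return w / np.abs(w).max()


def render_extracellular(
    trains: Sequence[tuple[SpikeTrain, float]],
    total_s: float,
    noise_sd: float = 0.0,
    sample_rate: float = 10_000.0,
    seed: int = 0,
) -> TimeSeries:
    """10 kHz extracellular voltage: amplitude-scaled biphasic templates
    at each spike time plus additive Gaussian noise.

    ``trains`` is a sequence of ``(SpikeTrain, amplitude)`` pairs; distinct
    amplitudes across units make the trace sortable by amplitude.
    """
    n = int(round(total_s * sample_rate))
    v = np.zeros(n)
    tmpl = _biphasic_template(sample_rate)
    half = tmpl.argmax()  # align template extremum to the spike time
    for train, amp in trains:
        for t_spk in train.times:
            if not 0 <= t_spk < total_s:
                raise InvalidInputError(f"spike at {t_spk} s outside trace span [0, {total_s}) s")
            i0 = int(round(t_spk * sample_rate)) - half
            lo, hi = max(0, i0), min(n, i0 + tmpl.size)
            v[lo:hi] += amp * tmpl[lo - i0 : hi - i0]
    if noise_sd > 0:
        v += np.random.default_rng(seed).normal(0.0, noise_sd, size=n)
    return TimeSeries(t0=0.0, sample_rate=sample_rate, values=v)


# ---------------------------------------------------------------------------
# fluorescence
# ---------------------------------------------------------------------------

def _soft_saturate(x: np.ndarray, sat_level: float) -> np.ndarray:
    """tanh-type compression; identity as sat_level → ∞."""
    if not np.isfinite(sat_level):
        return x
    if sat_level <= 0:
        raise InvalidParameterError("sat_level must be positive (or inf)")
    return sat_level * np.tanh(x / sat_level)


def _resample(ts: TimeSeries, frame_rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Linear resampling of a trace onto a new uniform grid."""
    n = int(round(ts.duration * frame_rate))
    t_new = ts.t0 + np.arange(n) / frame_rate
    return t_new, np.interp(t_new, ts.times, ts.values)


def render_arclight(
    drive: TimeSeries,
    scale: float = -0.05,
    sat_level: float = np.inf,
    bleach: BleachModel | None = None,
    noise_sd: float = 0.0,
    frame_rate: float = 125.0,
    drive_ref: float | None = None,
    seed: int = 0,
) -> TimeSeries:
    """Voltage-indicator fluorescence riding on a bleaching baseline.

    F(t) = b(t)·(1 + scale·sat(drive/drive_ref)) + noise.  The default
    ``scale`` is negative: the indicator dims on depolarization, so raw
    responses point downward and are sign-inverted after ΔF/F extraction.
    """
    if bleach is None:
        bleach = BleachModel(a_fast=120.0, a_slow=260.0, tau_fast_s=3.0, tau_slow_s=45.0, offset=650.0)
    if drive_ref is None:
        drive_ref = float(np.abs(drive.values).max()) or 1.0
    t, d = _resample(drive, frame_rate)
    resp = _soft_saturate(d / drive_ref, sat_level)
    f = bleach.baseline(t) * (1.0 + scale * resp)
    if noise_sd > 0:
        f = f + np.random.default_rng(seed).normal(0.0, noise_sd, size=f.size)
    return TimeSeries(t0=drive.t0, sample_rate=frame_rate, values=f)


def render_gcamp(
    rate: TimeSeries,
    ca_rise_s: float = 0.05,
    ca_decay_s: float = 1.0,
    bleach: BleachModel | None = None,
    noise_sd: float = 0.0,
    frame_rate: float = 40.0,
    scale: float = 0.8,
    sat_level: float = np.inf,
    drive_ref: float | None = None,
    seed: int = 0,
) -> TimeSeries:
    """Calcium-indicator fluorescence: rate convolved with a
    double-exponential calcium impulse kernel, on a bleach baseline.

    The slow decay of the calcium kernel makes calcium responses far more
    sustained than the underlying electrical activity.
    """
    if not ca_decay_s > ca_rise_s:
        raise InvalidParameterError("need ca_decay_s > ca_rise_s")
    if bleach is None:
        bleach = BleachModel(a_fast=80.0, a_slow=180.0, tau_fast_s=4.0, tau_slow_s=60.0, offset=900.0)
    dt = rate.dt
    tk = np.arange(0, 8.0 * ca_decay_s, dt)
    kernel = np.exp(-tk / ca_decay_s) - np.exp(-tk / ca_rise_s)
    kernel /= kernel.max()
    ca = np.convolve(rate.values, kernel)[: rate.n] * dt
    ca_ts = rate.copy_with(ca)
    if drive_ref is None:
        drive_ref = float(ca.max()) or 1.0
    t, d = _resample(ca_ts, frame_rate)
    resp = _soft_saturate(d / drive_ref, sat_level)
    f = bleach.baseline(t) * (1.0 + scale * resp)
    if noise_sd > 0:
        f = f + np.random.default_rng(seed).normal(0.0, noise_sd, size=f.size)
    return TimeSeries(t0=rate.t0, sample_rate=frame_rate, values=f)


def render_movie(
    trace: TimeSeries,
    roi_mask: np.ndarray,
    grid: tuple[int, int] = (80, 80),
    background: float = 100.0,
    pixel_noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Multi-frame grayscale movie with the trace painted into an ROI.

    ROI pixels carry the trace value plus independent pixel noise;
    non-ROI pixels carry the (already bleached) background plus noise.
    Returns an array of shape (n_frames, *grid); write with
    ``tifffile.imwrite`` for a multi-frame grayscale TIFF.
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != tuple(grid):
        raise InvalidParameterError(f"roi_mask shape {roi_mask.shape} != grid {grid}")
    if not roi_mask.any():
        raise InvalidParameterError("roi_mask must contain at least one pixel")
    n = trace.n
    stack = np.full((n, *grid), float(background))
    stack[:, roi_mask] = trace.values[:, None]
    if pixel_noise_sd > 0:
        stack += np.random.default_rng(seed).normal(0.0, pixel_noise_sd, size=stack.shape)
    return stack


def write_movie_tiff(stack: np.ndarray, path) -> None:
    """Write an image stack as a multi-frame grayscale TIFF (float32)."""
    import tifffile

    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))


def read_movie_tiff(path) -> np.ndarray:
    """Read a multi-frame grayscale TIFF into a (frames, rows, cols) array."""
    import tifffile

    stack = np.asarray(tifffile.imread(path), dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    return stack


# ---------------------------------------------------------------------------
# walking flies
# ---------------------------------------------------------------------------

def simulate_flies(
    n: int,
    arena: ArenaConfig,
    bp: BehaviorParams,
    pulses: Sequence[OdorPulseSpec],
    total_s: float,
    seed: int = 0,
    dropout_prob: float = 0.0,
    detection_noise_cm: float = 0.0,
    profile: Callable[[float], tuple[float, float]] = default_arena_profile,
) -> tuple[list[Trajectory], pd.DataFrame]:
    """Simulate ``n`` walking flies and the per-frame detection table.

    Per frame each fly takes a diffusive-heading step of speed
    ``base_speed`` plus a radial drift of magnitude ``drift_gain(c)``
    toward (positive) or away from (negative) the active port, where c is
    the local concentration sensed ``sensing_latency_s`` earlier; an
    engaged drift persists ``persistence_s`` after the concentration
    declines.  The boundary is reflective.

    Returns ground-truth trajectories and a detection table
    (frame, x_cm, y_cm, fly_id); detections can be degraded with dropout
    and position noise for tracker testing.
    """
    if n < 1:
        raise InvalidParameterError("need at least one fly")
    rng = np.random.default_rng(seed)
    fps = arena.frame_rate
    dt = 1.0 / fps
    n_frames = int(round(total_s * fps))
    port = arena.active_port_xy
    R = arena.radius_cm

    # concentration field c(distance, t): superpose the scheduled pulses
    # on a distance grid, then interpolate per fly per frame
    d_grid = np.linspace(0.0, 2 * R, 41)
    t_grid = np.arange(n_frames) * dt
    c_field = np.zeros((d_grid.size, n_frames))
    for spec in pulses:
        for j, d in enumerate(d_grid):
            ts = arena_pid(d, spec, profile=profile, total_s=total_s, sample_rate=fps,
                           arena_diameter_cm=2 * R)
            c_field[j] += ts.values[:n_frames]

    # initial positions uniform in the disk; initial headings uniform
    r0 = R * 0.95 * np.sqrt(rng.uniform(size=n))
    a0 = rng.uniform(0, 2 * np.pi, size=n)
    pos = np.column_stack([r0 * np.cos(a0), r0 * np.sin(a0)])
    heading = rng.uniform(0, 2 * np.pi, size=n)

    hold_value = np.zeros(n)
    hold_until = np.full(n, -np.inf)
    lag_frames = int(round(bp.sensing_latency_s * fps))

    xy = np.empty((n_frames, n, 2))
    noise_h = rng.normal(size=(n_frames, n))
    for k in range(n_frames):
        xy[k] = pos
        heading = heading + np.sqrt(bp.heading_diffusion * dt) * noise_h[k]
        step = bp.base_speed * dt * np.column_stack([np.cos(heading), np.sin(heading)])

        k_lag = max(0, k - lag_frames)
        to_port = port - pos
        dist = np.linalg.norm(to_port, axis=1)
        c_local = np.array(
            [np.interp(dist[i], d_grid, c_field[:, k_lag]) for i in range(n)]
        )
        raw = np.array([bp.drift_gain(c) for c in c_local])
        t_now = k * dt
        stronger = np.abs(raw) >= np.abs(hold_value)
        hold_value = np.where(stronger, raw, hold_value)
        hold_until = np.where(stronger, t_now + bp.persistence_s, hold_until)
        expired = t_now > hold_until
        hold_value = np.where(expired, raw, hold_value)
        effective = np.where(expired, raw, hold_value)

        with np.errstate(invalid="ignore", divide="ignore"):
            u_port = np.where(dist[:, None] > 1e-9, to_port / dist[:, None], 0.0)
        pos = pos + step + effective[:, None] * dt * u_port

        # reflective boundary
        rad = np.linalg.norm(pos, axis=1)
        out = rad > R
        if out.any():
            pos[out] = pos[out] * ((2 * R - rad[out]) / rad[out])[:, None]
            heading[out] = heading[out] + np.pi
            rad2 = np.linalg.norm(pos[out], axis=1)
            deep = rad2 > R  # pathological: started far outside; clamp
            if deep.any():
                sub = pos[out]
                sub[deep] = sub[deep] * (R / rad2[deep])[:, None] * 0.999
                pos[out] = sub

    trajs = [
        Trajectory(fly_id=i, frames=np.arange(n_frames), xy=xy[:, i, :]) for i in range(n)
    ]

    rows = []
    keep = rng.uniform(size=(n_frames, n)) >= dropout_prob
    det_noise = (
        rng.normal(0.0, detection_noise_cm, size=(n_frames, n, 2))
        if detection_noise_cm > 0
        else np.zeros((n_frames, n, 2))
    )
    for k in range(n_frames):
        for i in range(n):
            if keep[k, i]:
                rows.append((k, xy[k, i, 0] + det_noise[k, i, 0], xy[k, i, 1] + det_noise[k, i, 1], i))
    detections = pd.DataFrame(rows, columns=["frame", "x_cm", "y_cm", "fly_id"])
    return trajs, detections
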