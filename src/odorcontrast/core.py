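"""Core data containers shared by all analysis stages.

Every sampled signal in the package — photoionization-detector (PID) odor
traces, firing-rate traces, raw fluorescence, ΔF/F — is carried as a
:class:`TimeSeries`: a uniformly sampled vector with a start time and a
sample rate.  Spike trains, bleach-baseline parameters, and fly
trajectories get their own small containers.  All units are seconds, Hz,
and centimetres unless a field says otherwise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeries",
    "SpikeTrain",
    "BleachModel",
    "ArenaConfig",
    "Trajectory",
    "InvalidParameterError",
    "InvalidInputError",
    "FitFailureError",
    "UndefinedResultError",
]


class InvalidParameterError(ValueError):
    """A parameter violates its contract (non-positive rate, even width, ...)."""


class InvalidInputError(ValueError):
    """Input data violates a precondition (rate mismatch, empty mask, ...)."""


class FitFailureError(RuntimeError):
    """A model fit failed to converge; carries diagnostics in ``args``."""


class UndefinedResultError(ValueError):
    """The requested statistic is undefined for this input (e.g. zero reference)."""


@dataclass
class TimeSeries:
    """Uniformly sampled signal.

    Parameters
    ----------
    t0 : float
        Time of the first sample, in seconds.
    sample_rate : float
        Samples per second; must be positive.
    values : ndarray
        Sample values.  Units depend on context (PID a.u., Hz, fluorescence
        a.u., % ΔF/F).
    """

    t0: float
    sample_rate: float
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise InvalidParameterError(f"sample_rate must be > 0, got {self.sample_rate}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise InvalidInputError("values must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("values must be finite")

    # -- time axis -------------------------------------------------------
    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        return self.n * self.dt

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.sample_rate

    def index_at(self, t: float) -> int:
        """Nearest-sample index for time ``t`` (clipped to the trace span)."""
        i = int(round((t - self.t0) * self.sample_rate))
        if i < 0 or i >= self.n:
            raise InvalidInputError(
                f"time {t} s outside trace span [{self.t0}, {self.t0 + self.duration}) s"
            )
        return i

    def value_at(self, t: float) -> float:
        """Value at the sample nearest to time ``t``."""
        return float(self.values[self.index_at(t)])

    def window_slice(self, start_s: float, end_s: float) -> np.ndarray:
        """Values with times in ``[start_s, end_s)``."""
        t = self.times
        sel = (t >= start_s) & (t < end_s)
        if not sel.any():
            raise InvalidInputError(f"window [{start_s}, {end_s}) s contains no samples")
        return self.values[sel]

    def copy_with(self, values: np.ndarray) -> "TimeSeries":
        """Same time axis, new values (used by filters and detrending)."""
        return dataclasses.replace(self, values=np.asarray(values, dtype=float))

    # -- I/O -------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "value": self.values})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TimeSeries":
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy(float)
        if t.size < 2:
            raise InvalidInputError("need at least 2 samples to infer the sample rate")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise InvalidInputError("time_s column is not uniformly sampled")
        return cls(t0=float(t[0]), sample_rate=1.0 / float(dt[0]), values=df["value"].to_numpy(float))


@dataclass
class SpikeTrain:
    """Sorted event times for one unit, with per-event amplitudes (a.u.)."""

    unit_label: str
    times: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.times.size != self.amplitudes.size:
            raise InvalidInputError("times and amplitudes must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise InvalidInputError("spike times must be strictly increasing")

    @property
    def n(self) -> int:
        return self.times.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"unit": self.unit_label, "time_s": self.times, "amplitude": self.amplitudes}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class BleachModel:
    """Two-exponential-plus-offset photobleaching baseline.

    b(t) = a_fast · exp(−t/tau_fast_s) + a_slow · exp(−t/tau_slow_s) + offset
    """

    a_fast: float
    a_slow: float
    tau_fast_s: float
    tau_slow_s: float
    offset: float

    def __post_init__(self) -> None:
        if self.tau_fast_s <= 0 or self.tau_slow_s <= 0:
            raise InvalidParameterError("bleach time constants must be positive")
        if self.tau_fast_s > self.tau_slow_s:
            # keep the canonical ordering so parameters are comparable
            self.a_fast, self.a_slow = self.a_slow, self.a_fast
            self.tau_fast_s, self.tau_slow_s = self.tau_slow_s, self.tau_fast_s

    def baseline(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return (
            self.a_fast * np.exp(-t / self.tau_fast_s)
            + self.a_slow * np.exp(-t / self.tau_slow_s)
            + self.offset
        )


@dataclass
class ArenaConfig:
    """Circular walking arena with odor ports on the boundary.

    The standard arena is 10 cm in diameter with four ports spaced 90°
    apart on the rim and video collected at 30 frames per second.
    Coordinates are centimetres with the origin at the arena center.
    """

    radius_cm: float = 5.0
    n_ports: int = 4
    active_port: int = 0
    frame_rate: float = 30.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.radius_cm <= 0 or self.frame_rate <= 0:
            raise InvalidParameterError("radius_cm and frame_rate must be positive")
        if not 0 <= self.active_port < self.n_ports:
            raise InvalidParameterError("active_port out of range")

    @property
    def port_positions(self) -> np.ndarray:
        """(n_ports, 2) port coordinates, evenly spaced on the boundary."""
        ang = 2 * np.pi * np.arange(self.n_ports) / self.n_ports
        return self.radius_cm * np.column_stack([np.cos(ang), np.sin(ang)])

    @property
    def active_port_xy(self) -> np.ndarray:
        return self.port_positions[self.active_port]


@dataclass
class Trajectory:
    """Per-fly positions over frames, in arena coordinates (cm)."""

    fly_id: int
    frames: np.ndarray
    xy: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.shape != (self.frames.size, 2):
            raise InvalidInputError("xy must have shape (n_frames, 2)")
        if self.frames.size > 1 and not np.all(np.diff(self.frames) > 0):
            raise InvalidInputError("frames must be strictly increasing")

    @property
    def n(self) -> int:
        return self.frames.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": self.frames,
                "x_cm": self.xy[:, 0],
                "y_cm": self.xy[:, 1],
                "fly_id": self.fly_id,
            }
        )


def trajectories_to_csv(trajs: list, path) -> None:
    pd.concat([tr.to_frame() for tr in trajs], ignore_index=True).to_csv(path, index=False)


def trajectories_from_csv(path) -> list:
    df = pd.read_csv(path)
    out = []
    for fid, grp in df.groupby("fly_id"):
        grp = grp.sort_values("frame")
        out.append(
            Trajectory(
                fly_id=int(fid),
                frames=grp["frame"].to_numpy(int),
                xy=grp[["x_cm", "y_cm"]].to_numpy(float),
            )
        )
    return out
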