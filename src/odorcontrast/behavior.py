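"""Multi-fly tracking and odor-arena behavioral kinematics.

Per-frame detections are linked into trajectories with a constant-
velocity Kalman filter and greedy nearest-neighbor assignment.  From the
trajectories the module computes the study's kinematic statistics:

* d_t — distance from the active odor port over time;
* Δd_t = d_0 − d_t — displacement toward (+) or away (−) from the port
  since odor onset;
* the 0.5 s-binned mean-distance timecourse over 35 s (70 bins);
* signed radial velocity (positive = away from the port) in 1 s windows
  after pulse offset, stratified by initial distance (≤ 3 cm vs > 3 cm);
* net displacement Δd at pulse end, per fly and as group mean ± SEM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .core import InvalidInputError, InvalidParameterError, TimeSeries, Trajectory
from .synthgen import OdorPulseSpec

__all__ = [
    "Track",
    "kalman_track",
    "distance_to_port",
    "delta_d",
    "mean_distance_timecourse",
    "radial_velocity",
    "postpulse_kinetics",
    "net_displacement",
    "KineticsTable",
]


# ---------------------------------------------------------------------------
# constant-velocity Kalman filter (state = [x, y, vx, vy], measurement = [x, y])
# ---------------------------------------------------------------------------

def _cv_matrices(dt: float, q_process: float, r_meas: float):
    F = np.eye(4)
    F[0, 2] = F[1, 3] = dt
    H = np.zeros((2, 4))
    H[0, 0] = H[1, 1] = 1.0
    # discrete white-noise acceleration model
    q2, q3, q4 = dt**2, dt**3 / 2.0, dt**4 / 4.0
    Qb = np.array([[q4, q3], [q3, q2]]) * q_process
    Q = np.zeros((4, 4))
    Q[np.ix_([0, 2], [0, 2])] = Qb
    Q[np.ix_([1, 3], [1, 3])] = Qb
    R = np.eye(2) * r_meas**2
    return F, H, Q, R


class _KalmanTrack:
    """One track: filter state plus bookkeeping for birth/coasting."""

    def __init__(self, track_id: int, frame: int, z: np.ndarray, r_meas: float):
        self.id = track_id
        self.x = np.array([z[0], z[1], 0.0, 0.0])
        self.P = np.diag([r_meas**2, r_meas**2, 1.0, 1.0])
        self.frames = [frame]
        self.meas = [z.copy()]
        self.est = [z.copy()]
        self.hits = 1
        self.missed = 0
        self.confirmed = False

    def predict(self, F, Q):
        self.x = F @ self.x
        self.P = F @ self.P @ F.T + Q

    def update(self, z, H, R, frame):
        y = z - H @ self.x
        S = H @ self.P @ H.T + R
        K = self.P @ H.T @ np.linalg.inv(S)
        self.x = self.x + K @ y
        self.P = (np.eye(4) - K @ H) @ self.P
        self.frames.append(frame)
        self.meas.append(z.copy())
        self.est.append(self.x[:2].copy())
        self.hits += 1
        self.missed = 0

    def coast(self, frame):
        self.frames.append(frame)
        self.meas.append(self.x[:2].copy())  # predicted position stands in
        self.est.append(self.x[:2].copy())
        self.missed += 1


@dataclass
class Track(Trajectory):
    """Trajectory from the tracker; ``xy`` holds the assigned detection
    positions (predictions on coasted frames) and ``xy_filtered`` the
    Kalman position estimates."""

    xy_filtered: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))


def kalman_track(
    detections: pd.DataFrame,
    q_process: float = 1.0,
    r_meas: float = 0.05,
    gate_cm: float = 1.0,
    max_missed: int = 2,
    dt: float = 1.0 / 30.0,
    min_hits: int = 3,
    assignment: str = "greedy",
) -> list[Track]:
    """Link per-frame detections into trajectories.

    Per frame: predict all live tracks forward, assign detections to
    tracks by greedy nearest neighbor within ``gate_cm`` (ties broken by
    lower track id; ``assignment="hungarian"`` uses optimal assignment
    instead), update assigned tracks, coast unassigned tracks up to
    ``max_missed`` frames before terminating them, and seed new tracks
    from unassigned detections.  Tracks need ``min_hits`` consecutive
    supporting detections to be confirmed and reported.
    """
    if not {"frame", "x_cm", "y_cm"}.issubset(detections.columns):
        raise InvalidInputError("detections need columns frame, x_cm, y_cm")
    F, H, Q, R = _cv_matrices(dt, q_process, r_meas)
    live: list[_KalmanTrack] = []
    done: list[_KalmanTrack] = []
    next_id = 0

    by_frame = {int(f): g[["x_cm", "y_cm"]].to_numpy(float) for f, g in detections.groupby("frame")}
    if not by_frame:
        return []
    frames = range(min(by_frame), max(by_frame) + 1)

    for frame in frames:
        dets = by_frame.get(frame, np.empty((0, 2)))
        for tr in live:
            tr.predict(F, Q)

        assigned_det = set()
        assigned_trk = set()
        if live and dets.size:
            pred = np.array([tr.x[:2] for tr in live])
            D = np.linalg.norm(pred[:, None, :] - dets[None, :, :], axis=2)
            if assignment == "hungarian":
                big = 1e6
                cost = np.where(D <= gate_cm, D, big)
                rows, cols = linear_sum_assignment(cost)
                pairs = [(D[i, j], i, j) for i, j in zip(rows, cols) if D[i, j] <= gate_cm]
            else:  # greedy nearest neighbor, ties to the lower track id
                cand = [
                    (D[i, j], live[i].id, i, j)
                    for i in range(len(live))
                    for j in range(dets.shape[0])
                    if D[i, j] <= gate_cm
                ]
                cand.sort()
                pairs = []
                for d, _tid, i, j in cand:
                    if i in assigned_trk or j in assigned_det:
                        continue
                    pairs.append((d, i, j))
                    assigned_trk.add(i)
                    assigned_det.add(j)
            for _d, i, j in pairs:
                live[i].update(dets[j], H, R, frame)
                assigned_trk.add(i)
                assigned_det.add(j)

        survivors = []
        for i, tr in enumerate(live):
            if i in assigned_trk:
                survivors.append(tr)
                if tr.hits >= min_hits:
                    tr.confirmed = True
                continue
            if tr.hits < min_hits:  # tentative track lost support: drop it
                continue
            tr.coast(frame)
            if tr.missed > max_missed:
                # remove trailing coasted frames before closing out
                k = len(tr.frames) - tr.missed
                tr.frames, tr.meas, tr.est = tr.frames[:k], tr.meas[:k], tr.est[:k]
                done.append(tr)
            else:
                survivors.append(tr)
        live = survivors

        for j in range(dets.shape[0]):
            if j not in assigned_det:
                live.append(_KalmanTrack(next_id, frame, dets[j], r_meas))
                next_id += 1

    for tr in live:
        if tr.missed:
            k = len(tr.frames) - tr.missed
            tr.frames, tr.meas, tr.est = tr.frames[:k], tr.meas[:k], tr.est[:k]
        done.append(tr)

    out = []
    for tr in sorted(done, key=lambda t: t.id):
        if not tr.confirmed:
            continue
        out.append(
            Track(
                fly_id=tr.id,
                frames=np.asarray(tr.frames),
                xy=np.asarray(tr.meas),
                xy_filtered=np.asarray(tr.est),
            )
        )
    return out


# ---------------------------------------------------------------------------
# kinematics
# ---------------------------------------------------------------------------

def distance_to_port(traj: Trajectory, port: np.ndarray) -> np.ndarray:
    """Per-frame Euclidean distance (cm) from the fly to the odor port."""
    port = np.asarray(port, dtype=float)
    return np.linalg.norm(traj.xy - port[None, :], axis=1)


def delta_d(distances: np.ndarray, onset_index: int = 0) -> np.ndarray:
    """Δd_t = d_0 − d_t relative to the odor-onset sample.

    Positive values mean the fly moved toward the port (attraction),
    negative values away (avoidance).  Δd at onset is 0 by construction.
    """
    distances = np.asarray(distances, dtype=float)
    if not 0 <= onset_index < distances.size:
        raise InvalidInputError("onset_index outside the distance series")
    return distances[onset_index] - distances


def mean_distance_timecourse(
    trajs: list[Trajectory],
    port: np.ndarray,
    frame_rate: float = 30.0,
    bin_s: float = 0.5,
    total_s: float = 35.0,
) -> TimeSeries:
    """Mean distance from the port, sampled every ``bin_s`` over
    ``total_s`` (every 15 frames over 35 s at 30 fps → 70 bins).

    Bin k reports the across-fly mean distance at the sample
    ``k·bin_s``; trajectories that end early are dropped from later bins
    with a truncation warning.
    """
    step = int(round(bin_s * frame_rate))
    n_bins = int(round(total_s / bin_s))
    means = np.full(n_bins, np.nan)
    truncated = False
    for k in range(n_bins):
        frame = k * step
        vals = []
        for tr in trajs:
            pos = np.searchsorted(tr.frames, frame)
            if pos < tr.n and tr.frames[pos] == frame:
                vals.append(np.linalg.norm(tr.xy[pos] - port))
            else:
                truncated = True
        if vals:
            means[k] = np.mean(vals)
    if np.any(np.isnan(means)):  # no fly sampled at some bin: truncate there
        truncated = True
        means = means[: int(np.argmax(np.isnan(means)))]
        if means.size == 0:
            raise InvalidInputError("no trajectory covers even the first bin")
    if truncated:
        warnings.warn("some trajectories do not cover the full timecourse; bins truncated")
    return TimeSeries(t0=0.0, sample_rate=1.0 / bin_s, values=means)


def radial_velocity(
    traj: Trajectory,
    port: np.ndarray,
    window: tuple[float, float],
    frame_rate: float = 30.0,
) -> float:
    """Signed radial velocity over a time window, cm/s, positive = away
    from the port: (d(t1) − d(t0)) / (t1 − t0)."""
    t0, t1 = window
    if t1 <= t0:
        raise InvalidParameterError("window must have positive length")
    d = distance_to_port(traj, port)
    times = traj.frames / frame_rate

    def at(t):
        i = int(np.argmin(np.abs(times - t)))
        if abs(times[i] - t) > 1.5 / frame_rate:
            raise InvalidInputError(f"trajectory does not cover t={t} s")
        return d[i]

    return float((at(t1) - at(t0)) / (t1 - t0))


@dataclass
class KineticsTable:
    """Postpulse kinematics: one row per fly per window (``per_fly``) and
    group mean ± SEM per window per stratum (``summary``)."""

    per_fly: pd.DataFrame
    summary: pd.DataFrame


def postpulse_kinetics(
    trajs: list[Trajectory],
    port: np.ndarray,
    pulse: OdorPulseSpec,
    windows: list[tuple[float, float]] = ((0, 1), (1, 2), (2, 3), (3, 4)),
    strata_cm: float = 3.0,
    frame_rate: float = 30.0,
) -> KineticsTable:
    """Per-fly signed radial velocities in 1 s windows after pulse
    offset, stratified by each fly's distance from the port at odor onset
    (near: ≤ ``strata_cm``; far: > ``strata_cm``)."""
    onset_frame = int(round(pulse.onset_s * frame_rate))
    offset_s = pulse.offset_s
    rows = []
    for tr in trajs:
        pos = np.searchsorted(tr.frames, onset_frame)
        if pos >= tr.n or tr.frames[pos] != onset_frame:
            continue  # fly not tracked at odor onset
        d0 = float(np.linalg.norm(tr.xy[pos] - port))
        stratum = "near" if d0 <= strata_cm else "far"
        for w0, w1 in windows:
            try:
                v = radial_velocity(tr, port, (offset_s + w0, offset_s + w1), frame_rate)
            except InvalidInputError:
                continue
            rows.append(
                {
                    "fly_id": tr.fly_id,
                    "initial_distance_cm": d0,
                    "stratum": stratum,
                    "window": f"{w0}-{w1}",
                    "velocity_away_cm_s": v,
                }
            )
    per_fly = pd.DataFrame(rows)
    if per_fly.empty:
        return KineticsTable(per_fly=per_fly, summary=pd.DataFrame())
    summary = (
        per_fly.groupby(["stratum", "window"])["velocity_away_cm_s"]
        .agg(mean="mean", sem=lambda x: x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else np.nan,
             n="count")
        .reset_index()
    )
    for stratum in ("near", "far"):
        if stratum not in set(summary["stratum"]):
            warnings.warn(f"stratum {stratum!r} is empty; group statistics absent")
    return KineticsTable(per_fly=per_fly, summary=summary)


def net_displacement(
    trajs: list[Trajectory],
    port: np.ndarray,
    pulse_end_s: float,
    onset_s: float = 0.0,
    frame_rate: float = 30.0,
) -> pd.DataFrame:
    """Δd at the end of the pulse, per fly, with the group mean ± SEM in
    DataFrame attrs (``mean``, ``sem``).  Positive = net movement toward
    the port over the pulse."""
    onset_frame = int(round(onset_s * frame_rate))
    end_frame = int(round(pulse_end_s * frame_rate))
    rows = []
    for tr in trajs:
        i0 = np.searchsorted(tr.frames, onset_frame)
        i1 = np.searchsorted(tr.frames, end_frame)
        if i0 >= tr.n or i1 >= tr.n or tr.frames[i0] != onset_frame or tr.frames[i1] != end_frame:
            continue
        d = distance_to_port(tr, port)
        rows.append({"fly_id": tr.fly_id, "delta_d_cm": float(d[i0] - d[i1])})
    out = pd.DataFrame(rows)
    if not out.empty:
        out.attrs["mean"] = float(out["delta_d_cm"].mean())
        out.attrs["sem"] = (
            float(out["delta_d_cm"].std(ddof=1) / np.sqrt(len(out))) if len(out) > 1 else 0.0
        )
    else:
        out.attrs["mean"] = 0.0
        out.attrs["sem"] = 0.0
    return out
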