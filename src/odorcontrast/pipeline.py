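"""End-to-end scenarios: physiology (synthetic recordings → trace
processing → sharpness statistics) and behavior (fly simulation →
tracking statistics), driven by a single configuration object.

Genotype emulation maps receptor manipulations onto the presynaptic-
inhibition kernels: ``gA_off`` disables the fast kernel, ``gB_off`` the
slow kernel, ``both_off`` disables both; RNAi-enhancer ("dicer") variants
are emulated as weight scaling.  Every result table carries the seed and
a hash of the configuration so any output can be regenerated.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import behavior, contrast, synthgen, traceproc
from .core import ArenaConfig, InvalidParameterError
from .synthgen import BehaviorParams, InhibitionParams, OdorPulseSpec, OSNParams

__all__ = ["ScenarioConfig", "run_physiology", "run_behavior", "GENOTYPES"]

log = logging.getLogger("odorcontrast")

#: genotype label → (gA_enabled, gB_enabled, weight scale)
GENOTYPES = {
    "control": (True, True, 1.0),
    "gA_off": (False, True, 1.0),
    "gB_off": (True, False, 1.0),
    "both_off": (False, False, 1.0),
}


@dataclass
class ScenarioConfig:
    """Configuration for a physiology or behavior scenario run."""

    scenario: str = "physiology"
    #: dilution label → PID peak amplitude (a.u.); ordered weakest→strongest
    dilutions: dict = field(
        default_factory=lambda: {"1:125": 0.08, "1:25": 0.3, "1:5": 0.8, "1:1": 1.5}
    )
    genotypes: tuple = ("control", "gA_off", "gB_off", "both_off")
    seed: int = 0
    pulse_duration_s: float = 1.0
    pulse_onset_s: float = 2.0
    total_s: float = 8.0
    n_flies: int = 40
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.scenario not in ("physiology", "behavior"):
            raise InvalidParameterError(f"unknown scenario {self.scenario!r}")
        if not self.dilutions:
            raise InvalidParameterError("need at least one dilution")
        for g in self.genotypes:
            if g not in GENOTYPES:
                raise InvalidParameterError(f"unknown genotype {g!r}")

    @classmethod
    def from_file(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _stamp(df: pd.DataFrame, cfg: ScenarioConfig) -> pd.DataFrame:
    df["seed"] = cfg.seed
    df["config_hash"] = cfg.config_hash()
    return df


def _inhibition_for(genotype: str) -> InhibitionParams:
    gA, gB, w = GENOTYPES[genotype]
    base = InhibitionParams()
    return InhibitionParams(
        gA_weight=base.gA_weight * w,
        gA_tau_s=base.gA_tau_s,
        gB_weight=base.gB_weight * w,
        gB_tau_s=base.gB_tau_s,
        gA_enabled=gA,
        gB_enabled=gB,
    )


def run_physiology(config: ScenarioConfig) -> dict:
    """Simulate presynaptic voltage imaging per dilution × genotype and
    compute peak ΔF/F plus both sharpness statistics.

    Chain per condition: PID pulse → OSN rate (adaptation + sustained
    activity) → presynaptic inhibition per genotype → voltage-indicator
    rendering on a bleach baseline → bleach correction, smoothing, ΔF/F
    (sign-inverted so responses are positive) → sharpness statistics.

    Returns ``{"summary": DataFrame, "timecourse": DataFrame}``.
    """
    osn = OSNParams()
    rows, tc_rows = [], []
    delays = np.arange(0.1, 3.01, 0.1)
    for label, peak in config.dilutions.items():
        spec = OdorPulseSpec(
            onset_s=config.pulse_onset_s,
            duration_s=config.pulse_duration_s,
            peak=peak,
            dilution_label=label,
        )
        pid = synthgen.make_odor_pulse(spec, total_s=config.total_s, sample_rate=125.0)
        rate = synthgen.osn_rate(pid, osn)
        drive_ref = float(rate.values.max())  # common reference across genotypes
        for genotype in config.genotypes:
            t_start = time.perf_counter()
            inhibited = synthgen.apply_presynaptic_inhibition(rate, _inhibition_for(genotype))
            fluor = synthgen.render_arclight(inhibited, noise_sd=0.0, drive_ref=drive_ref)
            dff_trace = traceproc.process_trace(
                fluor,
                baseline_window=(0.0, spec.onset_s - 0.2),
                exclude_window=(spec.onset_s - 0.2, spec.offset_s + 4.0),
                invert=True,
            )
            s_max = contrast.sharpness_max(dff_trace, spec.offset_s, onset_time=spec.onset_s)
            s_off = contrast.sharpness_offset(dff_trace, spec.offset_s)
            rows.append(
                {
                    "dilution": label,
                    "genotype": genotype,
                    "peak_dff_pct": float(dff_trace.values.max()),
                    "sharpness_max": s_max.coefficient,
                    "sharpness_offset": s_off.coefficient,
                }
            )
            tc = contrast.sharpness_timecourse(dff_trace, spec.offset_s, delays)
            for d, cval in zip(delays, tc.values):
                tc_rows.append(
                    {"dilution": label, "genotype": genotype, "delay_s": float(d),
                     "sharpness_offset": float(cval)}
                )
            log.info(
                "physiology %s/%s: %d samples in %.2f s",
                label, genotype, dff_trace.n, time.perf_counter() - t_start,
            )
    return {
        "summary": _stamp(pd.DataFrame(rows), config),
        "timecourse": _stamp(pd.DataFrame(tc_rows), config),
    }


#: genotype emulation for behavior: knockdowns strengthen avoidance drive
#: and prolong postpulse persistence (avoidance gain scale, persistence add, s)
BEHAVIOR_GENOTYPE_EFFECTS = {
    "control": (1.0, 0.0),
    "gA_off": (1.4, 0.5),
    "gB_off": (1.0, 0.2),
    "both_off": (1.5, 1.5),
}


def run_behavior(config: ScenarioConfig) -> dict:
    """Simulate arena experiments per dilution × genotype and compute
    Δd timecourse, net displacement, and stratified postpulse velocities.

    Low dilutions drive attraction, high dilutions avoidance; receptor
    knockdowns are emulated as stronger, more persistent avoidance drive.
    Returns ``{"delta_d": DataFrame, "net": DataFrame, "kinetics": DataFrame}``.
    """
    arena = ArenaConfig()
    dd_rows, net_rows, kin_rows = [], [], []
    for label, peak in config.dilutions.items():
        attract = peak < 0.5  # weak stimuli attract, strong repel
        spec = OdorPulseSpec(
            onset_s=config.pulse_onset_s,
            duration_s=config.pulse_duration_s,
            peak=peak,
            dilution_label=label,
        )
        for genotype in config.genotypes:
            gain_scale, persist_add = BEHAVIOR_GENOTYPE_EFFECTS[genotype]
            if attract:
                drift = synthgen.attraction_drift(gain=0.8 / gain_scale)
            else:
                drift = synthgen.avoidance_drift(gain=1.2 * gain_scale)
            bp = BehaviorParams(
                base_speed=1.0,
                heading_diffusion=2.0,
                drift_gain=drift,
                persistence_s=0.5 + persist_add,
                sensing_latency_s=0.1,
            )
            tag = hashlib.sha256(f"{label}|{genotype}".encode()).digest()
            seed = (config.seed * 1_000_003 + int.from_bytes(tag[:4], "big")) % (2**31)
            trajs, _det = synthgen.simulate_flies(
                config.n_flies, arena, bp, [spec], total_s=config.total_s, seed=seed
            )
            port = arena.active_port_xy
            onset_frame = int(round(spec.onset_s * arena.frame_rate))
            for tr in trajs:
                d = behavior.distance_to_port(tr, port)
                dd = behavior.delta_d(d, onset_frame)
                for k in range(0, tr.n - onset_frame, 15):  # every 0.5 s
                    dd_rows.append(
                        {"dilution": label, "genotype": genotype, "fly_id": tr.fly_id,
                         "t_s": k / arena.frame_rate, "delta_d_cm": float(dd[onset_frame + k])}
                    )
            net = behavior.net_displacement(
                trajs, port, pulse_end_s=spec.offset_s, onset_s=spec.onset_s,
                frame_rate=arena.frame_rate,
            )
            net_rows.append(
                {"dilution": label, "genotype": genotype,
                 "mean_delta_d_cm": net.attrs["mean"], "sem": net.attrs["sem"],
                 "n": len(net)}
            )
            kt = behavior.postpulse_kinetics(trajs, port, spec, frame_rate=arena.frame_rate)
            if not kt.summary.empty:
                s = kt.summary.copy()
                s["dilution"] = label
                s["genotype"] = genotype
                kin_rows.append(s)
            log.info("behavior %s/%s: %d flies tracked", label, genotype, len(trajs))
    kinetics = pd.concat(kin_rows, ignore_index=True) if kin_rows else pd.DataFrame()
    return {
        "delta_d": _stamp(pd.DataFrame(dd_rows), config),
        "net": _stamp(pd.DataFrame(net_rows), config),
        "kinetics": _stamp(kinetics, config),
    }
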