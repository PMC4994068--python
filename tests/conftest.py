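import numpy as np
import pytest

from odorcontrast import synthgen as sg
from odorcontrast.core import ArenaConfig, BleachModel, TimeSeries


@pytest.fixture
def std_pulse() -> sg.OdorPulseSpec:
    """One-second supra-threshold pulse: the standard sustained-response
    stimulus (peak above the sustained-activity threshold of 0.5)."""
    return sg.OdorPulseSpec(onset_s=1.0, duration_s=1.0, peak=0.8, dilution_label="1:5")


@pytest.fixture
def weak_pulse() -> sg.OdorPulseSpec:
    """Sub-threshold pulse: evokes adaptation and poststimulus inhibition
    but no sustained component."""
    return sg.OdorPulseSpec(onset_s=1.0, duration_s=1.0, peak=0.3, dilution_label="1:25")


@pytest.fixture
def std_pid(std_pulse) -> TimeSeries:
    return sg.make_odor_pulse(std_pulse, total_s=8.0, sample_rate=125.0)


@pytest.fixture
def sustained_rate(std_pid) -> TimeSeries:
    """OSN rate with sustained postpulse activity (the sharpening target)."""
    return sg.osn_rate(std_pid, sg.OSNParams())


@pytest.fixture
def bleach() -> BleachModel:
    return BleachModel(a_fast=120.0, a_slow=260.0, tau_fast_s=3.0, tau_slow_s=45.0, offset=650.0)


@pytest.fixture
def arena() -> ArenaConfig:
    return ArenaConfig()


def exp_decay_trace(tau_s: float = 0.5, sample_rate: float = 125.0, total_s: float = 5.0,
                    peak: float = 1.0) -> TimeSeries:
    t = np.arange(int(total_s * sample_rate)) / sample_rate
    return TimeSeries(t0=0.0, sample_rate=sample_rate, values=peak * np.exp(-t / tau_s))
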