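"""Deliverable stimulation descriptions.

Converts an optimized phasor montage into ramped per-channel current
waveforms: channel k carries env(t) * |x_k| * cos(2 pi f t + phi_k) with
a linear ramp from 0 to 1 over the ramp-up period and back down at the
end.  Because the complex currents sum to zero, the instantaneous sum of
all channel currents vanishes at every sample.  Phase-to-time conversion
follows delay_ms = phase/360 * period; at the 80 Hz carrier a 90 degree
delay is 3.125 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .phasor_optimize import ComplexMontage

DEFAULT_RAMP_S = 30.0
DEFAULT_SAMPLE_RATE_HZ = 10_000.0
#: hardware safety note carried as plan metadata (no device control here)
IMPEDANCE_ABORT_KOHM = 20.0


def phase_to_time(phase_deg: float, frequency_hz: float) -> float:
    """Phase delay in milliseconds of one carrier cycle:
    (phase/360) * (1000/f)."""
    if frequency_hz <= 0:
        raise ValidationError("frequency must be positive")
    return phase_deg / 360.0 * 1000.0 / frequency_hz


@dataclass
class StimulationPlan:
    """A montage plus timing: carrier frequency, linear ramp durations,
    total duration and waveform sample rate."""

    montage: ComplexMontage
    duration_s: float
    ramp_s: float = DEFAULT_RAMP_S
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ
    metadata: dict = field(
        default_factory=lambda: {"impedance_abort_kohm": IMPEDANCE_ABORT_KOHM}
    )

    @property
    def frequency_hz(self) -> float:
        return self.montage.frequency_hz

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.ramp_s < 0:
            raise ValidationError("durations must be positive")
        if 2 * self.ramp_s >= self.duration_s:
            raise ValidationError("ramps must fit inside the total duration")
        if self.sample_rate_hz < 20 * self.frequency_hz:
            raise ValidationError(
                "sample rate must be at least 20x the carrier frequency"
            )


def envelope(t: np.ndarray, plan: StimulationPlan) -> np.ndarray:
    """Linear ramp-up / plateau / linear ramp-down envelope in [0, 1]."""
    up = np.clip(t / plan.ramp_s, 0.0, 1.0) if plan.ramp_s > 0 else np.ones_like(t)
    down = (
        np.clip((plan.duration_s - t) / plan.ramp_s, 0.0, 1.0)
        if plan.ramp_s > 0
        else np.ones_like(t)
    )
    return np.minimum(up, down)


def render_waveforms(plan: StimulationPlan) -> pd.DataFrame:
    """Sampled per-channel current traces (mA), wide format: column ``t``
    plus one column per electrode."""
    n = int(round(plan.duration_s * plan.sample_rate_hz)) + 1
    t = np.arange(n) / plan.sample_rate_hz
    env = envelope(t, plan)
    w = 2.0 * np.pi * plan.frequency_hz
    data = {"t": t}
    m = plan.montage
    for name, x in zip(m.names, m.currents_ma):
        data[name] = env * np.abs(x) * np.cos(w * t + np.angle(x))
    return pd.DataFrame(data)


def plateau_slice(plan: StimulationPlan, frame: pd.DataFrame) -> pd.DataFrame:
    """Rows of a rendered waveform strictly inside the plateau."""
    t = frame["t"].to_numpy()
    mask = (t >= plan.ramp_s) & (t <= plan.duration_s - plan.ramp_s)
    return frame.loc[mask]


def estimate_frequency(trace: np.ndarray, sample_rate_hz: float) -> float:
    """Carrier frequency estimate by zero-crossing counting on a plateau
    trace."""
    x = np.asarray(trace, dtype=float)
    s = np.sign(x)
    s[s == 0] = 1
    crossings = np.flatnonzero(np.diff(s))
    if len(crossings) < 2:
        raise ValidationError("trace too short to estimate frequency")
    span = (crossings[-1] - crossings[0]) / sample_rate_hz
    return (len(crossings) - 1) / (2.0 * span)
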