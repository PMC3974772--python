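"""Virtual olfactometer: flow arithmetic and synthesized PID traces.

The modelled instrument dilutes odorant in two stages.  A vial holds the
odorant at a liquid volume fraction in solvent; with an ideal-solution
(Raoult) headspace assumption the vial outlet carries that same fraction
of saturated vapor.  The vial stream (an *odor line*, 1–99 ml/min per
bank, or a 100 ml/min fixed line) then merges into a carrier stream, so
the airborne concentration is

    c_sv = liquid_dilution x odor_flow / total_flow        [saturated vapor]

A constant-total-flow rule removes mechanical stimulation artifacts: the
carrier setpoint drops by exactly the summed open odor-line flows for the
duration of a pulse, keeping total flow constant throughout.

Concentration at the detector is synthesized as a first-order system: an
exponential rise toward the plateau while a valve is open (shared time
constant, the instrument's rise is fast regardless of odor), and after
valve close an exponential clearance whose time constant shrinks with the
odorant's vapor pressure — volatile odors clear the tubing faster.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OdorSpec",
    "FlowConfig",
    "ValvePulse",
    "ValveTimeline",
    "PidTrace",
    "DEFAULT_ODORS",
    "airborne_dilution",
    "carrier_flow",
    "max_combined_bank_flow",
    "count_binary_mixtures",
    "clearance_tau_s",
    "simulate_pid_trace",
    "flow_profile",
]

#: Rise time constant while a valve is open (s); fast and odor-independent.
RISE_TAU_S = 0.2
#: Clearance tau = CLEARANCE_COEF / vapor_pressure_mmHg, clipped below.
CLEARANCE_COEF = 8.0
#: Clip range for the clearance time constant (s).  The 2.1 s ceiling
#: guarantees the signal falls below 1% of plateau within 10 s of valve
#: close (exp(-10/2.1) ~ 0.9%) for even the least volatile odorant.
CLEARANCE_TAU_RANGE_S = (0.2, 2.1)


@dataclass(frozen=True)
class OdorSpec:
    """An odor vial: odorant name, liquid dilution, and volatility."""

    name: str
    liquid_dilution: float  # volume fraction in solvent, (0, 1]
    vapor_pressure_mmhg: float
    solvent: str = "mineral_oil"  # "mineral_oil" | "water"

    def __post_init__(self):
        if not 0 < self.liquid_dilution <= 1:
            raise ValueError(f"liquid_dilution must be in (0, 1], got {self.liquid_dilution}")
        if self.vapor_pressure_mmhg <= 0:
            raise ValueError(f"vapor_pressure_mmhg must be > 0, got {self.vapor_pressure_mmhg}")
        if self.solvent not in ("mineral_oil", "water"):
            raise ValueError(f"unknown solvent {self.solvent!r}")


#: Stock odor set with literature vapor pressures (mmHg): isoamylamine,
#: 2-hexanone, amyl acetate, heptanal.  Liquid dilution defaults to 1:1000.
DEFAULT_ODORS: dict[str, OdorSpec] = {
    "IAMM": OdorSpec("IAMM", 1e-3, 51.1),
    "HXO": OdorSpec("HXO", 1e-3, 12.0),
    "AA": OdorSpec("AA", 1e-3, 4.0),
    "HPH": OdorSpec("HPH", 1e-3, 3.0),
}


@dataclass(frozen=True)
class FlowConfig:
    """Olfactometer flow topology and limits (ml/min)."""

    carrier_setpoint_ml_min: float = 1000.0
    fixed_line_ml_min: float = 100.0
    variable_line_range: tuple[float, float] = (1.0, 99.0)
    n_banks: int = 2
    vials_per_bank: int = 4

    def __post_init__(self):
        if self.carrier_setpoint_ml_min < 0 or self.fixed_line_ml_min < 0:
            raise ValueError("flows must be >= 0")
        lo, hi = self.variable_line_range
        if not 0 <= lo <= hi:
            raise ValueError(f"bad variable_line_range {self.variable_line_range}")
        if self.n_banks < 1 or self.vials_per_bank < 1:
            raise ValueError("n_banks and vials_per_bank must be >= 1")


@dataclass(frozen=True)
class ValvePulse:
    """One odor-valve opening: which vial, when, and at what line flow."""

    odor: str
    onset_ms: int
    offset_ms: int
    flow_ml_min: float = 100.0

    def __post_init__(self):
        if self.offset_ms <= self.onset_ms:
            raise ValueError(f"offset_ms ({self.offset_ms}) must exceed onset_ms ({self.onset_ms})")
        if self.flow_ml_min <= 0:
            raise ValueError("flow_ml_min must be > 0")


@dataclass
class ValveTimeline:
    """A sequence of valve pulses driving the instrument."""

    pulses: list[ValvePulse] = field(default_factory=list)

    @property
    def end_ms(self) -> int:
        return max((p.offset_ms for p in self.pulses), default=0)

    def to_json(self) -> str:
        return json.dumps(
            [
                {
                    "odor": p.odor,
                    "onset_ms": p.onset_ms,
                    "offset_ms": p.offset_ms,
                    "flow_ml_min": p.flow_ml_min,
                }
                for p in self.pulses
            ],
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "ValveTimeline":
        return cls([ValvePulse(**d) for d in json.loads(text)])


@dataclass
class PidTrace:
    """A synthesized photo-ionization detector trace (arbitrary units)."""

    dt_ms: int
    samples: np.ndarray

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.dt_ms < 1:
            raise ValueError("dt_ms must be >= 1")
        if not np.all(np.isfinite(self.samples)) or np.any(self.samples < 0):
            raise ValueError("PID samples must be finite and >= 0")

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(len(self.samples)) * (self.dt_ms / 1000.0)

    def value_at(self, t_ms: float) -> float:
        """Sample nearest to ``t_ms``."""
        i = int(round(t_ms / self.dt_ms))
        return float(self.samples[min(max(i, 0), len(self.samples) - 1)])

    def to_tsv(self) -> str:
        lines = ["time_s\tsignal"]
        for t, s in zip(self.times_s, self.samples):
            lines.append(f"{t:.6g}\t{s:.6g}")
        return "\n".join(lines) + "\n"


def airborne_dilution(spec: OdorSpec, odor_flow_ml_min: float, total_flow_ml_min: float) -> float:
    """Airborne concentration (fraction of saturated vapor) after in-line dilution."""
    if total_flow_ml_min <= 0:
        raise ValueError("total_flow_ml_min must be > 0")
    if not 0 < odor_flow_ml_min <= total_flow_ml_min:
        raise ValueError(
            f"odor flow ({odor_flow_ml_min}) must be in (0, total flow = {total_flow_ml_min}]"
        )
    return spec.liquid_dilution * odor_flow_ml_min / total_flow_ml_min


def carrier_flow(total_setpoint_ml_min: float, open_odor_flows: list[float]) -> float:
    """Carrier flow keeping total flow at the setpoint while odor lines are open."""
    total_odor = sum(open_odor_flows)
    if total_odor > total_setpoint_ml_min:
        raise ValueError(
            f"open odor flows ({total_odor} ml/min) exceed setpoint ({total_setpoint_ml_min})"
        )
    return total_setpoint_ml_min - total_odor


def max_combined_bank_flow(config: FlowConfig) -> float:
    """Maximum summed variable-line flow across all banks (ml/min)."""
    return config.n_banks * config.variable_line_range[1]


def count_binary_mixtures(config: FlowConfig) -> int:
    """Number of distinct two-odor mixtures, one vial drawn per bank."""
    if config.n_banks != 2:
        raise ValueError(f"binary mixtures require exactly 2 banks, config has {config.n_banks}")
    return config.vials_per_bank**2


def clearance_tau_s(spec: OdorSpec) -> float:
    """Post-valve clearance time constant (s), decreasing with vapor pressure."""
    lo, hi = CLEARANCE_TAU_RANGE_S
    return min(max(CLEARANCE_COEF / spec.vapor_pressure_mmhg, lo), hi)


def simulate_pid_trace(
    timeline: ValveTimeline,
    specs: dict[str, OdorSpec],
    config: FlowConfig | None = None,
    dt_ms: int = 10,
    gain_per_odor: dict[str, float] | None = None,
    duration_ms: int | None = None,
) -> PidTrace:
    """Synthesize the detector trace driven by a valve timeline.

    Each odor contributes a first-order response: exponential rise toward
    ``gain x airborne_dilution`` while its valve is open, exponential
    clearance after close.  Contributions of overlapping odors superpose.
    No vial depletion is modelled (repeated pulses give equal plateaus).
    """
    config = config or FlowConfig()
    gain_per_odor = gain_per_odor or {}
    for p in timeline.pulses:
        if p.odor not in specs:
            raise KeyError(f"unknown odor id {p.odor!r} in timeline")
    if duration_ms is None:
        duration_ms = timeline.end_ms + 15_000
    n = int(duration_ms // dt_ms) + 1
    total = np.zeros(n)
    dt_s = dt_ms / 1000.0
    for odor in {p.odor for p in timeline.pulses}:
        spec = specs[odor]
        gain = gain_per_odor.get(odor, 1.0)
        tau_c = clearance_tau_s(spec)
        pulses = sorted((p for p in timeline.pulses if p.odor == odor), key=lambda p: p.onset_ms)
        sig = np.empty(n)
        s = 0.0
        rise_step = math.exp(-dt_s / RISE_TAU_S)
        clear_step = math.exp(-dt_s / tau_c)
        for i in range(n):
            t_ms = i * dt_ms
            open_pulse = next((p for p in pulses if p.onset_ms <= t_ms < p.offset_ms), None)
            if open_pulse is not None:
                plateau = gain * airborne_dilution(
                    spec, open_pulse.flow_ml_min, config.carrier_setpoint_ml_min
                )
                s = plateau + (s - plateau) * rise_step
            else:
                s = s * clear_step
            sig[i] = s
        total += sig
    return PidTrace(dt_ms=dt_ms, samples=total)


def flow_profile(
    timeline: ValveTimeline, config: FlowConfig | None = None, dt_ms: int = 10
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Carrier and total flow over time under the constant-total-flow rule.

    Returns ``(times_s, carrier_ml_min, total_ml_min)``; the total is the
    carrier plus all open odor lines and is constant by construction.
    """
    config = config or FlowConfig()
    n = int((timeline.end_ms + 5_000) // dt_ms) + 1
    times = np.arange(n) * (dt_ms / 1000.0)
    carrier = np.empty(n)
    total = np.empty(n)
    for i in range(n):
        t_ms = i * dt_ms
        open_flows = [p.flow_ml_min for p in timeline.pulses if p.onset_ms <= t_ms < p.offset_ms]
        carrier[i] = carrier_flow(config.carrier_setpoint_ml_min, open_flows)
        total[i] = carrier[i] + sum(open_flows)
    return times, carrier, total
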