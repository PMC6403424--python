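"""Energy-input protocols: timed heat pulses and UV windows.

A protocol is an ordered list of events.  A heat pulse instantaneously
re-activates part of the inactive pool (fuelling); a UV pulse opens a short
window during which both relaxation rates are multiplied by the UV factor,
collapsing the chains within minutes.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

from .errors import ConfigurationError

#: Default UV window: five minutes, in days.
UV_DEFAULT_DURATION_DAYS = 5.0 / (60.0 * 24.0)

HEAT_PULSE = "heat_pulse"
UV_PULSE = "uv_pulse"


@dataclass(frozen=True)
class ProtocolEvent:
    """One energy-input event.

    ``params`` may override ``efficiency`` (heat) or ``duration_days`` /
    ``factor`` (UV).
    """
    time: float
    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in (HEAT_PULSE, UV_PULSE):
            raise ConfigurationError(f"unknown event kind {self.kind!r}")
        if self.time < 0:
            raise ConfigurationError(f"event time must be >= 0, got {self.time}")


@dataclass(frozen=True)
class Protocol:
    """Ordered sequence of energy-input events with strictly increasing times."""

    events: tuple[ProtocolEvent, ...] = ()

    def __post_init__(self):
        times = [e.time for e in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ConfigurationError("event times must be strictly increasing")

    def __add__(self, other: "Protocol") -> "Protocol":
        merged = sorted(self.events + other.events, key=lambda e: e.time)
        return Protocol(tuple(merged))

    def __len__(self) -> int:
        return len(self.events)

    def to_list(self) -> list[dict]:
        return [
            {"time_days": e.time, "kind": e.kind, **copy.deepcopy(e.params)}
            for e in self.events
        ]

    @classmethod
    def from_list(cls, items: list[dict]) -> "Protocol":
        events = []
        for it in items:
            it = dict(it)
            t = float(it.pop("time_days"))
            kind = it.pop("kind")
            events.append(ProtocolEvent(t, kind, it))
        return cls(tuple(events))


def single_fuel(t0: float = 0.0, efficiency: float | None = None) -> Protocol:
    """One heat pulse at time ``t0`` (days)."""
    params = {} if efficiency is None else {"efficiency": efficiency}
    return Protocol((ProtocolEvent(t0, HEAT_PULSE, params),))


def repeated_fuel(period: float = 4.0, n_cycles: int = 2, t0: float = 0.0) -> Protocol:
    """Heat pulses at ``t0, t0+period, …`` — ``n_cycles`` pulses in total.

    The 4-day default period refuels the system just before depolymerization
    would take over, sustaining the active state indefinitely.
    """
    if period <= 0:
        raise ConfigurationError(f"period must be > 0, got {period}")
    if n_cycles < 1:
        raise ConfigurationError(f"n_cycles must be >= 1, got {n_cycles}")
    return Protocol(tuple(
        ProtocolEvent(t0 + i * period, HEAT_PULSE) for i in range(n_cycles)
    ))


def uv_quench(
    t_uv: float,
    duration: float = UV_DEFAULT_DURATION_DAYS,
    factor: float | None = None,
) -> Protocol:
    """A UV pulse covering ``[t_uv, t_uv + duration]`` (days).

    During the window both relaxation rates are multiplied by ``factor``
    (defaulting to the rate set's ``uv_factor``), so the chains scission
    away within minutes instead of days.
    """
    if t_uv < 0:
        raise ConfigurationError(f"t_uv must be >= 0, got {t_uv}")
    if duration <= 0:
        raise ConfigurationError(f"duration must be > 0, got {duration}")
    params = {"duration_days": duration}
    if factor is not None:
        params["factor"] = factor
    return Protocol((ProtocolEvent(t_uv, UV_PULSE, params),))


def concentration_sweep(config, factors: list[float]) -> list:
    """Scaled copies of a run configuration for a concentration series.

    Each factor scales the initial unit count (and total concentration) at
    fixed volume; seeds are shared across the batch so trajectories can be
    compared pairwise.
    """
    out = []
    for f in factors:
        if f <= 0:
            raise ConfigurationError(f"concentration factors must be > 0, got {f}")
        c = copy.deepcopy(config)
        c["initial"] = dict(c.get("initial", {}))
        c["initial"]["total_units"] = int(round(c["initial"].get("total_units", 10_000) * f))
        c["initial"]["total_concentration_uM"] = (
            float(c["initial"].get("total_concentration_uM", 30.0)) * f
        )
        out.append(c)
    return out
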