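"""Exact stochastic simulation (direct-method Gillespie) of the network.

Per-chain reaction channels are aggregated by class — one propensity per
channel kind, with a secondary draw selecting the chain and scission site —
so the channel count stays constant while chains may number in the
hundreds.  Protocol events (heat pulses, UV windows) interrupt the chain of
exponential waiting times at their scheduled instants; the memorylessness
of the process makes restarting the clock at a boundary exact.

Reproducibility contract: identical inputs and seed give bit-identical
event sequences (NumPy PCG64 generator, explicit integer seeds everywhere).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, NumericalError
from .network import build_reaction_network, apply_heat_pulse
from .observables import mean_chain_length
from .params import RateParameters
from .protocols import HEAT_PULSE, UV_PULSE, Protocol, UV_DEFAULT_DURATION_DAYS
from .state import SystemState

__all__ = ["SimulationResult", "EnsembleResult", "simulate", "run_ensemble", "spawn_seeds"]


@dataclass
class SimulationResult:
    """One stochastic trajectory, snapshotted at the requested record times."""

    record_times: np.ndarray
    states: list[SystemState]
    event_count: int
    seed: int
    params: RateParameters | None = None

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for t, s in zip(self.record_times, self.states):
            rows.append({
                "time_days": t,
                "n_inactive": s.n_inactive,
                "n_active_closed": s.n_active_closed,
                "n_active_open": s.n_active_open,
                "n_chains": len(s.chains),
                "chain_units": s.chain_units,
                "total_units": s.total_units,
                "mean_length_chains": mean_chain_length(s, "chains_only"),
                "mean_length_all": mean_chain_length(s, "all_assemblies"),
                "active_fraction": s.active_fraction,
            })
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_json(self, path=None) -> str:
        """Full serialization including the chain-length multisets."""
        payload = {
            "seed": int(self.seed),
            "event_count": int(self.event_count),
            "snapshots": [
                {
                    "time_days": float(t),
                    "n_inactive": s.n_inactive,
                    "n_active_closed": s.n_active_closed,
                    "n_active_open": s.n_active_open,
                    "chains": sorted(s.chains),
                    "volume_litres": s.volume_litres,
                }
                for t, s in zip(self.record_times, self.states)
            ],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _expand_boundaries(protocol: Protocol, params: RateParameters, t_end: float):
    """Turn protocol events into a sorted list of (time, action, payload)."""
    bounds = []
    for ev in protocol.events:
        if ev.time > t_end:
            continue
        if ev.kind == HEAT_PULSE:
            bounds.append((ev.time, "heat", ev.params.get("efficiency")))
        elif ev.kind == UV_PULSE:
            dur = float(ev.params.get("duration_days", UV_DEFAULT_DURATION_DAYS))
            fac = float(ev.params.get("factor", params.uv_factor))
            bounds.append((ev.time, "uv_on", fac))
            bounds.append((min(ev.time + dur, t_end), "uv_off", None))
    bounds.sort(key=lambda b: b[0])
    bounds.append((t_end, "end", None))
    return bounds


def simulate(
    initial: SystemState,
    params: RateParameters,
    protocol: Protocol,
    t_end: float,
    record_times,
    seed: int,
) -> SimulationResult:
    """Run one exact SSA trajectory from ``initial`` to ``t_end`` (days).

    Snapshots are taken at ``record_times``; a record time coinciding with a
    protocol event reports the post-event state (so a pulse at t = 0 is
    visible in the first record).
    """
    if t_end <= 0:
        raise ConfigurationError(f"t_end must be > 0, got {t_end}")
    rec = np.sort(np.asarray(record_times, dtype=float))
    if rec.size and (rec[0] < initial.time - 1e-9 or rec[-1] > t_end + 1e-9):
        raise ConfigurationError("record_times must lie within [t_start, t_end]")

    rng = np.random.default_rng(int(seed))
    channels = build_reaction_network(params)
    props = [c.propensity for c in channels]
    applies = [c.apply for c in channels]
    n_ch = len(channels)

    state = initial.copy()
    t = state.time
    bounds = _expand_boundaries(protocol, params, t_end)
    snapshots: list[SystemState] = []
    snap_t: list[float] = []
    ri = 0
    uv_depth = 0
    p_eff = params
    event_count = 0
    rand = rng.random
    rexp = rng.standard_exponential

    def record_before(t_new):
        nonlocal ri
        while ri < rec.size and rec[ri] < t_new:
            snap = state.copy()
            snap.time = float(rec[ri])
            snapshots.append(snap)
            snap_t.append(float(rec[ri]))
            ri += 1

    def record_at(t_b):
        nonlocal ri
        while ri < rec.size and rec[ri] <= t_b:
            snap = state.copy()
            snap.time = float(rec[ri])
            snapshots.append(snap)
            snap_t.append(float(rec[ri]))
            ri += 1

    for bt, action, payload in bounds:
        if bt < t:
            # event scheduled before the initial time: skip
            continue
        # SSA segment on [t, bt)
        while True:
            a = [f(state, p_eff) for f in props]
            atot = 0.0
            for x in a:
                atot += x
            if not math.isfinite(atot):
                raise NumericalError(
                    f"non-finite total propensity at t={t}: {a}; state dump: "
                    f"I={state.n_inactive} A={state.n_active_closed} "
                    f"O={state.n_active_open} chains={len(state.chains)}"
                )
            if atot <= 0.0:
                t = bt
                break
            t_next = t + rexp() / atot
            if t_next >= bt:
                t = bt
                break
            record_before(t_next)
            u = rand() * atot
            k = 0
            acc = a[0]
            while u > acc and k < n_ch - 1:
                k += 1
                acc += a[k]
            applies[k](state, p_eff, rng)
            event_count += 1
            t = t_next
            state.time = t
        # boundary reached
        record_before(bt)
        state.time = bt
        if action == "heat":
            apply_heat_pulse(state, params, payload)
        elif action == "uv_on":
            uv_depth += 1
            p_eff = params.with_uv(payload)
        elif action == "uv_off":
            uv_depth -= 1
            if uv_depth <= 0:
                p_eff = params
        record_at(bt)

    return SimulationResult(
        record_times=np.asarray(snap_t),
        states=snapshots,
        event_count=event_count,
        seed=int(seed),
        params=params,
    )


def spawn_seeds(seed_base: int, n: int) -> list[int]:
    """Derive ``n`` independent 31-bit integer seeds from ``seed_base``."""
    children = np.random.SeedSequence(int(seed_base)).spawn(n)
    return [int(c.generate_state(1)[0] & 0x7FFFFFFF) for c in children]


@dataclass
class EnsembleResult:
    """Replicate trajectories plus per-time summary statistics."""

    results: list[SimulationResult]
    seeds: list[int]
    seed_base: int

    @property
    def record_times(self) -> np.ndarray:
        return self.results[0].record_times

    def summary(self) -> pd.DataFrame:
        """Per-time mean and sd (over replicates) of the main observables."""
        frames = [r.to_dataframe() for r in self.results]
        stacked = pd.concat(frames, keys=range(len(frames)), names=["rep"])
        cols = [
            "mean_length_chains", "mean_length_all", "active_fraction",
            "n_chains", "chain_units", "n_inactive", "n_active_closed",
            "n_active_open",
        ]
        g = stacked.groupby("time_days")
        out = pd.DataFrame({"time_days": sorted(stacked["time_days"].unique())})
        out = out.set_index("time_days")
        for c in cols:
            out[f"{c}_mean"] = g[c].mean()
            out[f"{c}_sd"] = g[c].std(ddof=1) if len(frames) > 1 else 0.0
        return out.reset_index()

    def states_at(self, time: float) -> list[SystemState]:
        """The replicate snapshots closest to ``time``."""
        out = []
        for r in self.results:
            i = int(np.argmin(np.abs(r.record_times - time)))
            out.append(r.states[i])
        return out


def run_ensemble(
    n_reps: int,
    seed_base: int,
    initial: SystemState,
    params: RateParameters,
    protocol: Protocol,
    t_end: float,
    record_times,
) -> EnsembleResult:
    """Run ``n_reps`` independent trajectories with deterministically derived seeds."""
    if n_reps < 1:
        raise ConfigurationError(f"n_reps must be >= 1, got {n_reps}")
    seeds = spawn_seeds(seed_base, n_reps)
    results = [
        simulate(initial, params, protocol, t_end, record_times, seed=s)
        for s in seeds
    ]
    return EnsembleResult(results=results, seeds=seeds, seed_base=int(seed_base))
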