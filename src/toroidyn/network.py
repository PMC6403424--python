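"""Reaction network of the polymerization–depolymerization cycle.

The model couples three dynamic processes:

1. *Activation / relaxation* — heat pulses convert static (eclipsed) toroids
   into the kinetically trapped active (slipped) state; active free toroids
   relax back first order (``relax_free``).
2. *Nucleation – elongation – joining* — active closed toroids open into a
   spiral (``open``/``close``); two open spirals nucleate a chain slowly
   (``nucleate``); chains grow fast by capturing open toroids (``elongate``)
   and may merge end-to-end (``join``).  Cooperativity (k_el ≫ k_nuc)
   produces the lag phase.
3. *Scission-driven collapse* — each in-chain subunit relaxes first order
   (``relax_scission``); the relaxed subunit leaves the chain as an inactive
   free toroid and the chain breaks at that position, chosen uniformly at
   random, fragmenting the polymer until only intact toroids remain.

Bimolecular propensities use count combinatorics with the volume-scaled
stochastic rate ``k / Ω`` where ``Ω = units_per_uM`` of the state, so the
deterministic limit of channel fluxes matches the mean-field solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .errors import ConfigurationError, NumericalError
from .params import RateParameters
from .state import SystemState

__all__ = [
    "ReactionChannel",
    "build_reaction_network",
    "apply_channel",
    "apply_heat_pulse",
    "CHANNEL_NAMES",
]

CHANNEL_NAMES = (
    "open", "close", "relax_free", "nucleate", "elongate", "join", "relax_scission",
)


@dataclass(frozen=True)
class ReactionChannel:
    """One reaction channel: a propensity law plus a state-update rule.

    ``propensity(state, params)`` returns events/day; ``apply(state, params,
    rng)`` mutates the state in place, drawing any secondary choices (which
    chain, which scission site) from ``rng``.  Every apply rule conserves
    total toroid units.
    """

    name: str
    propensity: Callable[[SystemState, RateParameters], float]
    apply: Callable[[SystemState, RateParameters, np.random.Generator], None]


# --- propensity laws -------------------------------------------------------

def _p_open(s: SystemState, p: RateParameters) -> float:
    return p.k_open * s.n_active_closed


def _p_close(s: SystemState, p: RateParameters) -> float:
    return p.k_close * s.n_active_open


def _p_relax_free(s: SystemState, p: RateParameters) -> float:
    # Only closed active toroids relax; open spirals must close first.
    return p.k_relax_free * s.n_active_closed


def _p_nucleate(s: SystemState, p: RateParameters) -> float:
    o = s.n_active_open
    return p.k_nuc / s.units_per_uM * o * (o - 1) / 2.0 if o >= 2 else 0.0


def _p_elongate(s: SystemState, p: RateParameters) -> float:
    # Chain ends are equivalent and saturating: one capture channel per chain.
    return p.k_el / s.units_per_uM * len(s.chains) * s.n_active_open


def _p_join(s: SystemState, p: RateParameters) -> float:
    n = len(s.chains)
    return p.k_join / s.units_per_uM * n * (n - 1) / 2.0 if n >= 2 else 0.0


def _p_relax_scission(s: SystemState, p: RateParameters) -> float:
    return p.k_relax_chain * s.chain_units


# --- state updates ---------------------------------------------------------

def _a_open(s: SystemState, p: RateParameters, rng) -> None:
    s.n_active_closed -= 1
    s.n_active_open += 1


def _a_close(s: SystemState, p: RateParameters, rng) -> None:
    s.n_active_open -= 1
    s.n_active_closed += 1


def _a_relax_free(s: SystemState, p: RateParameters, rng) -> None:
    s.n_active_closed -= 1
    s.n_inactive += 1


def _a_nucleate(s: SystemState, p: RateParameters, rng) -> None:
    s.n_active_open -= 2
    s.chains.append(2)
    s.chain_units += 2


def _a_elongate(s: SystemState, p: RateParameters, rng) -> None:
    i = int(rng.integers(len(s.chains)))
    s.chains[i] += 1
    s.chain_units += 1
    s.n_active_open -= 1


def _a_join(s: SystemState, p: RateParameters, rng) -> None:
    n = len(s.chains)
    i = int(rng.integers(n))
    j = int(rng.integers(n - 1))
    if j >= i:
        j += 1
    if j < i:
        i, j = j, i
    s.chains[i] += s.chains[j]
    s.chains[j] = s.chains[-1]
    s.chains.pop()


def _a_relax_scission(s: SystemState, p: RateParameters, rng) -> None:
    """Relax one in-chain subunit, chosen uniformly over all in-chain units.

    The chain is therefore picked with probability proportional to its
    length, the site uniformly within the chain.  The relaxed subunit leaves
    as an inactive free toroid; the two flanking fragments survive as chains
    (length ≥ 2), re-enter the open pool (length 1) or vanish (length 0).
    """
    u = int(rng.integers(s.chain_units))
    acc = 0
    for i, n in enumerate(s.chains):
        acc += n
        if u < acc:
            break
    site = n - (acc - u)          # 0-based site within chain i, uniform
    left, right = site, n - site - 1
    s.chains[i] = s.chains[-1]
    s.chains.pop()
    s.chain_units -= n
    s.n_inactive += 1
    for frag in (left, right):
        if frag >= 2:
            s.chains.append(frag)
            s.chain_units += frag
        elif frag == 1:
            s.n_active_open += 1


_CHANNELS = {
    "open": (_p_open, _a_open),
    "close": (_p_close, _a_close),
    "relax_free": (_p_relax_free, _a_relax_free),
    "nucleate": (_p_nucleate, _a_nucleate),
    "elongate": (_p_elongate, _a_elongate),
    "join": (_p_join, _a_join),
    "relax_scission": (_p_relax_scission, _a_relax_scission),
}


def build_reaction_network(params: RateParameters) -> list[ReactionChannel]:
    """Return the full channel list of the kinetic model.

    Parameters are validated first; an invalid field raises
    :class:`~toroidyn.errors.ConfigurationError` naming it.
    """
    params.validate()
    return [ReactionChannel(name, prop, app) for name, (prop, app) in _CHANNELS.items()]


def apply_channel(
    state: SystemState,
    channel: ReactionChannel,
    params: RateParameters,
    rng: np.random.Generator,
) -> SystemState:
    """Fire ``channel`` once on ``state`` (in place) and return the state.

    Precondition: the channel's propensity is > 0 on the state.  Violations
    indicate an engine bug and raise :class:`NumericalError`.
    """
    if channel.propensity(state, params) <= 0:
        raise NumericalError(
            f"channel {channel.name!r} applied to a state with zero propensity"
        )
    channel.apply(state, params, rng)
    return state


def apply_heat_pulse(
    state: SystemState,
    params: RateParameters,
    efficiency: float | None = None,
) -> SystemState:
    """Instantaneous heat pulse: activate part of the inactive pool (in place).

    ``floor(n_inactive × efficiency)`` toroids move to the active closed
    state; the remainder stays inactive.  In-chain subunits are active by
    construction and are untouched, as are existing chains — the toroids'
    ring structure survives heating intact.
    """
    eff = params.activation_efficiency if efficiency is None else efficiency
    if not 0.0 <= eff <= 1.0:
        raise ConfigurationError(f"activation efficiency must be in [0, 1], got {eff}")
    moved = math.floor(state.n_inactive * eff)
    state.n_inactive -= moved
    state.n_active_closed += moved
    return state
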