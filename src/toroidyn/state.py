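"""System state of the stochastic model: species counts plus chain multiset."""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigurationError
from .params import N_AVOGADRO


def volume_for(total_units: int, total_concentration_uM: float) -> float:
    """Effective reaction volume (litres) mapping a concentration to a count.

    Chosen so that ``total_concentration_uM`` corresponds to exactly
    ``total_units`` toroid units; the default desk-scale configuration maps
    30 μM to 10,000 units.
    """
    if total_units <= 0 or total_concentration_uM <= 0:
        raise ConfigurationError("total_units and total_concentration_uM must be > 0")
    return total_units / (total_concentration_uM * 1e-6 * N_AVOGADRO)


@dataclass
class SystemState:
    """Counts of free toroid species plus the multiset of active chain lengths.

    Attributes
    ----------
    time : float
        Simulation time (days).
    n_inactive : int
        Static free toroids (eclipsed packing, closed).
    n_active_closed : int
        Heat-activated free toroids, closed ring.
    n_active_open : int
        Activated free toroids in the spirally open conformation.
    chains : list of int
        Lengths (in toroid units, each ≥ 2) of the active helical chains.
    volume_litres : float
        Effective reaction volume converting concentrations to counts.
    chain_units : int
        Cached total number of in-chain toroid units; kept in sync by the
        reaction-channel apply rules (see :meth:`validate`).
    """

    time: float
    n_inactive: int
    n_active_closed: int
    n_active_open: int
    chains: list[int] = field(default_factory=list)
    volume_litres: float = volume_for(10_000, 30.0)
    chain_units: int = field(default=-1)

    def __post_init__(self) -> None:
        if self.chain_units < 0:
            self.chain_units = sum(self.chains)
        if min(self.n_inactive, self.n_active_closed, self.n_active_open, 0) < 0:
            raise ConfigurationError("species counts must be >= 0")
        if any(n < 2 for n in self.chains):
            raise ConfigurationError("every chain length must be >= 2")
        if self.volume_litres <= 0:
            raise ConfigurationError("volume_litres must be > 0")

    # ------------------------------------------------------------------

    @classmethod
    def from_concentration(
        cls,
        total_concentration_uM: float = 30.0,
        total_units: int = 10_000,
        active_fraction: float = 0.0,
        time: float = 0.0,
    ) -> "SystemState":
        """All-monomer initial state at a given concentration and desk scale.

        ``active_fraction`` of the units start as active closed toroids (as
        immediately after a heat pulse); the rest are inactive.
        """
        if not 0.0 <= active_fraction <= 1.0:
            raise ConfigurationError("active_fraction must be in [0, 1]")
        n_active = int(round(total_units * active_fraction))
        return cls(
            time=time,
            n_inactive=total_units - n_active,
            n_active_closed=n_active,
            n_active_open=0,
            chains=[],
            volume_litres=volume_for(total_units, total_concentration_uM),
        )

    # ------------------------------------------------------------------

    @property
    def units_per_uM(self) -> float:
        """Number of toroid units corresponding to 1 μM in this volume."""
        return self.volume_litres * 1e-6 * N_AVOGADRO

    @property
    def total_units(self) -> int:
        """Total toroid units over all species; conserved by every channel."""
        return (self.n_inactive + self.n_active_closed
                + self.n_active_open + self.chain_units)

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    @property
    def n_free(self) -> int:
        return self.n_inactive + self.n_active_closed + self.n_active_open

    @property
    def active_units(self) -> int:
        """Units in the kinetically trapped (slipped) state: free active
        toroids plus every in-chain subunit."""
        return self.n_active_closed + self.n_active_open + self.chain_units

    @property
    def active_fraction(self) -> float:
        total = self.total_units
        return self.active_units / total if total else 0.0

    def concentration_uM(self, count: float) -> float:
        return count / self.units_per_uM

    def copy(self) -> "SystemState":
        return SystemState(
            time=self.time,
            n_inactive=self.n_inactive,
            n_active_closed=self.n_active_closed,
            n_active_open=self.n_active_open,
            chains=list(self.chains),
            volume_litres=self.volume_litres,
            chain_units=self.chain_units,
        )

    def validate(self) -> None:
        """Check internal consistency (cached totals, count positivity)."""
        assert self.chain_units == sum(self.chains), "chain_units cache out of sync"
        assert self.n_inactive >= 0 and self.n_active_closed >= 0 \
            and self.n_active_open >= 0, "negative species count"
        assert all(n >= 2 for n in self.chains), "chain shorter than 2 units"
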