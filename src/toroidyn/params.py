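"""Rate parameters and toroid geometry parameters.

Units convention used throughout the package: time in days, lengths in nm,
concentrations in micromolar (μM).  First-order rate constants are per day;
bimolecular rate constants are per μM per day and are converted to stochastic
(count-based) rates through the effective reaction volume carried by the
system state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

from .errors import ConfigurationError

#: Equilibrium constant of the spirally open form over the closed toroid.
#: The default rate pair (k_open, k_close) is constrained to this ratio.
OPEN_CLOSE_EQUILIBRIUM_K = 5.5e-3

#: Avogadro's number (1/mol).
N_AVOGADRO = 6.02214076e23


@dataclass(frozen=True)
class RateParameters:
    """Kinetic rate constants of the polymerization–depolymerization network.

    Parameters
    ----------
    k_open : float
        Closed → open spiral transition rate of an active toroid (per day).
    k_close : float
        Open → closed transition rate (per day).
    k_nuc : float
        Bimolecular nucleation rate, open + open → chain of two
        (per μM per day).
    k_el : float
        Bimolecular elongation rate, chain end + open toroid
        (per μM per day).
    k_join : float
        Bimolecular end-to-end chain–chain joining rate (per μM per day).
        Set to 0 to disable joining.
    k_relax_free : float
        First-order relaxation (active → inactive) of free closed toroids
        (per day).  Governs the slow recovery of the CD signal.
    k_relax_chain : float
        Per-subunit first-order relaxation rate of in-chain toroids
        (per day).  A relaxed in-chain subunit immediately causes chain
        scission and leaves as an inactive free toroid.
    uv_factor : float
        Dimensionless multiplier (≥ 1) applied to both relaxation rates
        while a UV pulse is on.
    activation_efficiency : float
        Fraction in [0, 1] of the inactive pool converted to the active
        closed state by one heat pulse.
    """

    k_open: float
    k_close: float
    k_nuc: float
    k_el: float
    k_join: float
    k_relax_free: float
    k_relax_chain: float
    uv_factor: float = 1.0
    activation_efficiency: float = 1.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, (int, float)) or not math.isfinite(v):
                raise ConfigurationError(f"{f.name} must be a finite number, got {v!r}")
        for name in ("k_open", "k_close", "k_nuc", "k_el", "k_join",
                     "k_relax_free", "k_relax_chain"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.uv_factor < 1:
            raise ConfigurationError(f"uv_factor must be >= 1, got {self.uv_factor}")
        if not 0.0 <= self.activation_efficiency <= 1.0:
            raise ConfigurationError(
                f"activation_efficiency must be in [0, 1], got {self.activation_efficiency}"
            )

    @property
    def open_close_K(self) -> float:
        """Equilibrium constant of the open over the closed form."""
        if self.k_close == 0:
            return math.inf
        return self.k_open / self.k_close

    @property
    def cooperativity(self) -> float:
        """Elongation-to-nucleation rate ratio (∞ for k_nuc = 0)."""
        if self.k_nuc == 0:
            return math.inf
        return self.k_el / self.k_nuc

    def with_uv(self, factor: float | None = None) -> "RateParameters":
        """Return a copy with both relaxation rates multiplied by the UV factor."""
        f = self.uv_factor if factor is None else factor
        if f < 1:
            raise ConfigurationError(f"uv factor must be >= 1, got {f}")
        return replace(
            self,
            k_relax_free=self.k_relax_free * f,
            k_relax_chain=self.k_relax_chain * f,
        )

    def replace(self, **kw) -> "RateParameters":
        return replace(self, **kw)

    # --- serialization with explicit units in the key names -----------------

    _KEYMAP = {
        "k_open": "k_open_per_day",
        "k_close": "k_close_per_day",
        "k_nuc": "k_nuc_per_uM_per_day",
        "k_el": "k_el_per_uM_per_day",
        "k_join": "k_join_per_uM_per_day",
        "k_relax_free": "k_relax_free_per_day",
        "k_relax_chain": "k_relax_chain_per_day",
        "uv_factor": "uv_factor",
        "activation_efficiency": "activation_efficiency",
    }

    def to_dict(self) -> dict:
        return {self._KEYMAP[f.name]: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "RateParameters":
        inv = {v: k for k, v in cls._KEYMAP.items()}
        unknown = set(d) - set(inv)
        if unknown:
            raise ConfigurationError(f"unknown rate keys: {sorted(unknown)}")
        missing = set(inv) - set(d)
        if missing:
            raise ConfigurationError(f"missing rate keys: {sorted(missing)}")
        return cls(**{inv[k]: float(v) for k, v in d.items()})


_CHIRALITY_ALIASES = {
    "S": 1, "s": 1, "+1": 1, 1: 1,
    "R": -1, "r": -1, "-1": -1, -1: -1,
    "racemic": 0, "rac": 0, "0": 0, 0: 0,
}


@dataclass(frozen=True)
class ToroidGeometry:
    """Geometric parameters of a single toroid and of the helices it forms.

    The toroid is a closed ring with external diameter ``external_diameter``
    built from a tube of diameter ``tube_diameter``; when spirally open it
    contributes one helical turn of pitch ``pitch`` to a growing chain.
    ``chirality`` is +1 for the S enantiomer (right-handed helices), −1 for
    the R enantiomer (left-handed), 0 for a racemic mixture (which cannot
    polymerize).
    """

    external_diameter: float = 12.0   # nm
    tube_diameter: float = 3.0        # nm (assumption, not a printed value)
    pitch: float = 3.0                # nm per turn; close-packed turns
    chirality: int = 1

    def __post_init__(self) -> None:
        if not self.external_diameter > self.tube_diameter > 0:
            raise ConfigurationError(
                "require external_diameter > tube_diameter > 0, got "
                f"{self.external_diameter} and {self.tube_diameter}"
            )
        if self.pitch <= 0:
            raise ConfigurationError(f"pitch must be > 0, got {self.pitch}")
        if self.chirality not in (-1, 0, 1):
            raise ConfigurationError(f"chirality must be -1, 0 or +1, got {self.chirality}")

    @property
    def centerline_radius(self) -> float:
        """Radius of the tube centerline circle (nm)."""
        return (self.external_diameter - self.tube_diameter) / 2.0

    @staticmethod
    def parse_chirality(value) -> int:
        try:
            return _CHIRALITY_ALIASES[value]
        except KeyError:
            raise ConfigurationError(
                f"chirality must be one of S, R, racemic, +1, -1, 0; got {value!r}"
            ) from None

    def to_dict(self) -> dict:
        return {
            "external_diameter_nm": self.external_diameter,
            "tube_diameter_nm": self.tube_diameter,
            "pitch_nm": self.pitch,
            "chirality": self.chirality,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ToroidGeometry":
        allowed = {"external_diameter_nm", "tube_diameter_nm", "pitch_nm", "chirality"}
        unknown = set(d) - allowed
        if unknown:
            raise ConfigurationError(f"unknown geometry keys: {sorted(unknown)}")
        return cls(
            external_diameter=float(d.get("external_diameter_nm", 12.0)),
            tube_diameter=float(d.get("tube_diameter_nm", 3.0)),
            pitch=float(d.get("pitch_nm", 3.0)),
            chirality=cls.parse_chirality(d.get("chirality", "S")),
        )
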