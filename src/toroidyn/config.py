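"""Run configuration: schema-validated YAML/JSON describing a full run.

All times are in days, lengths in nm, concentrations in μM; rate keys carry
their units in the key name.  Unknown keys are rejected so typos fail loudly
before any computation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .defaults import (
    DEFAULT_CONCENTRATION_UM,
    DEFAULT_RATES,
    DEFAULT_T_END,
    DEFAULT_TOTAL_UNITS,
)
from .errors import SchemaError
from .params import RateParameters, ToroidGeometry
from .protocols import Protocol, single_fuel
from .state import SystemState

__all__ = ["RunConfig", "CONFIG_SCHEMA_VERSION"]

CONFIG_SCHEMA_VERSION = 1

_TOP_KEYS = {
    "schema_version", "rates", "initial", "protocol", "geometry",
    "observables", "simulation", "seed",
}
_INITIAL_KEYS = {"total_concentration_uM", "total_units", "active_fraction"}
_OBS_KEYS = {
    "mean_length_mode", "cd_baseline", "cd_amplitude",
    "include_monomers", "cryotem_n", "cryotem_log_sd",
}
_SIM_KEYS = {"t_end_days", "record_every_days", "n_reps", "n_max"}


def _check_keys(d: dict, allowed: set, where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise SchemaError(f"unknown keys under {where}: {sorted(unknown)}")


@dataclass
class RunConfig:
    """Validated run configuration with derived builders."""

    rates: RateParameters = DEFAULT_RATES
    total_concentration_uM: float = DEFAULT_CONCENTRATION_UM
    total_units: int = DEFAULT_TOTAL_UNITS
    active_fraction: float = 0.0
    protocol: Protocol = field(default_factory=lambda: single_fuel(0.0))
    geometry: ToroidGeometry = field(default_factory=ToroidGeometry)
    mean_length_mode: str = "all_assemblies"
    cd_baseline: float = 0.0
    cd_amplitude: float = 1.0
    include_monomers: bool = True
    cryotem_n: int = 100
    cryotem_log_sd: float = 0.1
    t_end_days: float = DEFAULT_T_END
    record_every_days: float = 0.25
    n_reps: int = 1
    n_max: int = 4000
    seed: int | None = None

    # ------------------------------------------------------------------

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        if not isinstance(d, dict):
            raise SchemaError("config root must be a mapping")
        _check_keys(d, _TOP_KEYS, "config root")
        version = d.get("schema_version")
        if version != CONFIG_SCHEMA_VERSION:
            raise SchemaError(
                f"config schema_version {version!r} does not match supported "
                f"version {CONFIG_SCHEMA_VERSION}"
            )
        kw: dict = {}
        if "rates" in d:
            kw["rates"] = RateParameters.from_dict(d["rates"])
        if "initial" in d:
            _check_keys(d["initial"], _INITIAL_KEYS, "initial")
            ini = d["initial"]
            kw["total_concentration_uM"] = float(
                ini.get("total_concentration_uM", DEFAULT_CONCENTRATION_UM))
            kw["total_units"] = int(ini.get("total_units", DEFAULT_TOTAL_UNITS))
            kw["active_fraction"] = float(ini.get("active_fraction", 0.0))
        if "protocol" in d:
            kw["protocol"] = Protocol.from_list(d["protocol"])
        if "geometry" in d:
            kw["geometry"] = ToroidGeometry.from_dict(d["geometry"])
        if "observables" in d:
            _check_keys(d["observables"], _OBS_KEYS, "observables")
            kw.update({k: d["observables"][k] for k in d["observables"]})
        if "simulation" in d:
            _check_keys(d["simulation"], _SIM_KEYS, "simulation")
            kw.update({k.replace("t_end_days", "t_end_days"): d["simulation"][k]
                       for k in d["simulation"]})
        if "seed" in d and d["seed"] is not None:
            kw["seed"] = int(d["seed"])
        return cls(**kw)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith(".json"):
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return {
            "schema_version": CONFIG_SCHEMA_VERSION,
            "rates": self.rates.to_dict(),
            "initial": {
                "total_concentration_uM": self.total_concentration_uM,
                "total_units": self.total_units,
                "active_fraction": self.active_fraction,
            },
            "protocol": self.protocol.to_list(),
            "geometry": self.geometry.to_dict(),
            "observables": {
                "mean_length_mode": self.mean_length_mode,
                "cd_baseline": self.cd_baseline,
                "cd_amplitude": self.cd_amplitude,
                "include_monomers": self.include_monomers,
                "cryotem_n": self.cryotem_n,
                "cryotem_log_sd": self.cryotem_log_sd,
            },
            "simulation": {
                "t_end_days": self.t_end_days,
                "record_every_days": self.record_every_days,
                "n_reps": self.n_reps,
                "n_max": self.n_max,
            },
            "seed": self.seed,
        }

    def to_yaml(self, path=None) -> str:
        header = (
            "# toroidyn run configuration\n"
            "# units: times in days, lengths in nm, concentrations in uM\n"
        )
        text = header + yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    # ------------------------------------------------------------------

    def initial_state(self) -> SystemState:
        return SystemState.from_concentration(
            self.total_concentration_uM, self.total_units, self.active_fraction,
        )

    def record_times(self) -> np.ndarray:
        return np.arange(0.0, self.t_end_days + 1e-9, self.record_every_days)

    def content_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()
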