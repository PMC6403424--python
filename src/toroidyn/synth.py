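"""Synthetic experimental datasets with the noise structure the fits assume.

One stochastic trajectory is measured the way the laboratory streams are:
per-time-point cryo-TEM samples of n assembly lengths with multiplicative
log-normal measurement error, a CD trace with additive Gaussian noise, and
a DLS trace with relative Gaussian noise.  The generating trajectory is
stored alongside as ground truth, and the whole dataset is reproducible
bit-for-bit from its metadata (parameters, protocol, seed, noise settings).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .defaults import DEFAULT_CONCENTRATION_UM, DEFAULT_RATES, DEFAULT_TOTAL_UNITS
from .errors import ConfigurationError, SchemaError
from .observables import record_from_state, sample_cryotem
from .params import RateParameters, ToroidGeometry
from .protocols import Protocol, single_fuel
from .ssa import simulate
from .state import SystemState

__all__ = ["SyntheticDataset", "generate", "write_dataset", "read_dataset", "DEFAULT_NOISE"]

SCHEMA_VERSION = 1

DEFAULT_NOISE = {
    "cryotem_log_sd": 0.1,   # sd of log length, multiplicative error
    "cd_sd": 0.02,           # additive, in units of the CD amplitude
    "dls_rel_sd": 0.05,      # relative error of the reported diameter
}

_TABLES = ("cryotem", "cd_trace", "dls_trace", "truth")
_FILENAMES = {
    "cryotem": "cryotem.csv",
    "cd_trace": "cd.csv",
    "dls_trace": "dls.csv",
    "truth": "truth.csv",
}


@dataclass
class SyntheticDataset:
    """Noisy observable tables plus the generating ground truth."""

    metadata: dict
    cryotem: pd.DataFrame     # time_days, replicate, length_nm
    cd_trace: pd.DataFrame    # time_days, cd_signal
    dls_trace: pd.DataFrame   # time_days, diameter_nm
    truth: pd.DataFrame       # one row per sample time, noise-free observables

    def to_fit_frame(self) -> pd.DataFrame:
        """Collapse the cryo-TEM samples into the calibration CSV schema
        (time_days, mean_length_nm, mean_length_se, cd_signal)."""
        g = self.cryotem.groupby("time_days")["length_nm"]
        out = pd.DataFrame({
            "time_days": sorted(self.cryotem["time_days"].unique()),
        })
        out["mean_length_nm"] = g.mean().to_numpy()
        out["mean_length_se"] = (g.std(ddof=1) / np.sqrt(g.count())).to_numpy()
        out = out.merge(self.cd_trace, on="time_days", how="left")
        return out


def generate(
    params: RateParameters = DEFAULT_RATES,
    protocol: Protocol | None = None,
    sample_times=(0, 1, 2, 3, 4, 5, 6, 8, 10, 12),
    n_per_time: int = 100,
    noise: dict | None = None,
    seed: int = 0,
    total_units: int = DEFAULT_TOTAL_UNITS,
    total_concentration_uM: float = DEFAULT_CONCENTRATION_UM,
    geometry: ToroidGeometry | None = None,
    include_monomers: bool = True,
    cd_baseline: float = 0.0,
    cd_amplitude: float = 1.0,
) -> SyntheticDataset:
    """Simulate one trajectory and measure it with experimental noise.

    ``n_per_time`` defaults to 100 assemblies per time point, the size of
    the micrograph counts the analysis emulates.  Setting every noise
    entry to zero makes the observed tables equal the truth exactly.
    """
    protocol = protocol if protocol is not None else single_fuel(0.0)
    g = geometry or ToroidGeometry()
    nz = dict(DEFAULT_NOISE)
    nz.update(noise or {})
    unknown = set(nz) - set(DEFAULT_NOISE)
    if unknown:
        raise ConfigurationError(f"unknown noise keys: {sorted(unknown)}")
    times = np.sort(np.asarray(sample_times, dtype=float))
    t_end = float(times.max()) if times.max() > 0 else 1.0

    init = SystemState.from_concentration(total_concentration_uM, total_units)
    traj = simulate(init, params, protocol, t_end, times, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), SCHEMA_VERSION]))

    truth_rows, cryo_rows, cd_rows, dls_rows = [], [], [], []
    for t, state in zip(traj.record_times, traj.states):
        rec = record_from_state(state, g, mode="all_assemblies",
                                cd_baseline=cd_baseline, cd_amplitude=cd_amplitude)
        truth_rows.append({
            "time_days": t,
            "mean_length_units": rec.mean_length_units,
            "mean_length_nm": rec.mean_length_nm,
            "active_fraction": rec.active_fraction,
            "cd_signal": rec.cd_signal,
            "dls_diameter_nm": rec.dls_diameter_nm,
        })
        lengths = sample_cryotem(
            state, n=n_per_time, noise_sd_log=nz["cryotem_log_sd"], rng=rng,
            include_monomers=include_monomers, geometry=g,
        )
        for k, L in enumerate(lengths):
            cryo_rows.append({"time_days": t, "replicate": k, "length_nm": float(L)})
        cd_rows.append({
            "time_days": t,
            "cd_signal": rec.cd_signal
            + cd_amplitude * nz["cd_sd"] * rng.standard_normal(),
        })
        dls_rows.append({
            "time_days": t,
            "diameter_nm": rec.dls_diameter_nm
            * (1.0 + nz["dls_rel_sd"] * rng.standard_normal()),
        })

    metadata = {
        "schema_version": SCHEMA_VERSION,
        "rates": params.to_dict(),
        "protocol": protocol.to_list(),
        "geometry": g.to_dict(),
        "sample_times_days": times.tolist(),
        "n_per_time": int(n_per_time),
        "noise": nz,
        "seed": int(seed),
        "total_units": int(total_units),
        "total_concentration_uM": float(total_concentration_uM),
        "include_monomers": bool(include_monomers),
        "cd_baseline": float(cd_baseline),
        "cd_amplitude": float(cd_amplitude),
        "ssa_event_count": int(traj.event_count),
    }
    return SyntheticDataset(
        metadata=metadata,
        cryotem=pd.DataFrame(cryo_rows),
        cd_trace=pd.DataFrame(cd_rows),
        dls_trace=pd.DataFrame(dls_rows),
        truth=pd.DataFrame(truth_rows),
    )


def regenerate(metadata: dict) -> SyntheticDataset:
    """Rebuild a dataset from its manifest metadata (bit-identical)."""
    return generate(
        params=RateParameters.from_dict(metadata["rates"]),
        protocol=Protocol.from_list(metadata["protocol"]),
        sample_times=metadata["sample_times_days"],
        n_per_time=metadata["n_per_time"],
        noise=metadata["noise"],
        seed=metadata["seed"],
        total_units=metadata["total_units"],
        total_concentration_uM=metadata["total_concentration_uM"],
        geometry=ToroidGeometry.from_dict(metadata["geometry"]),
        include_monomers=metadata["include_monomers"],
        cd_baseline=metadata["cd_baseline"],
        cd_amplitude=metadata["cd_amplitude"],
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_dataset(dataset: SyntheticDataset, path) -> None:
    """Write manifest.json plus the four CSV tables with checksums."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    checksums = {}
    for name in _TABLES:
        fname = _FILENAMES[name]
        getattr(dataset, name).to_csv(root / fname, index=False)
        checksums[fname] = _sha256(root / fname)
    manifest = {"metadata": dataset.metadata, "checksums": checksums}
    (root / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_dataset(path) -> SyntheticDataset:
    """Lossless round-trip read with schema and checksum validation."""
    root = Path(path)
    mf = root / "manifest.json"
    if not mf.exists():
        raise SchemaError(f"no manifest.json under {root}")
    manifest = json.loads(mf.read_text())
    meta = manifest.get("metadata", {})
    version = meta.get("schema_version")
    if version != SCHEMA_VERSION:
        raise SchemaError(
            f"dataset schema_version {version!r} does not match supported "
            f"version {SCHEMA_VERSION}"
        )
    tables = {}
    for name in _TABLES:
        fname = _FILENAMES[name]
        fpath = root / fname
        if not fpath.exists():
            raise SchemaError(f"missing table {fname}")
        digest = _sha256(fpath)
        if digest != manifest["checksums"].get(fname):
            raise SchemaError(f"checksum mismatch for {fname}: file was modified")
        tables[name] = pd.read_csv(fpath)
    return SyntheticDataset(metadata=meta, **tables)
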