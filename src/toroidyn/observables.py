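"""Map simulated states onto measured quantities.

Three experimental streams are proxied:

* **cryo-TEM** — chain-length statistics: mean assembly length (in toroid
  units or nm) and per-time-point samples of n assemblies with measurement
  noise;
* **CD** — an affine function of the fraction of subunits in the chirally
  slipped (active) state, so a pure first-order relaxation gives the
  observed first-order signal decay;
* **DLS** — an intensity-weighted hydrodynamic diameter using the sphere
  rule for single toroids and a short-rigid-rod approximation for helical
  chains.  This conversion is a documented proxy, not a printed calibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .params import ToroidGeometry
from .state import SystemState

__all__ = [
    "TimeSeriesRecord",
    "mean_chain_length",
    "cd_proxy",
    "length_to_nm",
    "nm_to_length",
    "hydrodynamic_diameter",
    "dls_proxy",
    "sample_cryotem",
    "record_from_state",
]

#: End-correction constant of the short-rod hydrodynamic formula
#: D_h = L / (ln(L/d) + 0.32).
ROD_END_CORRECTION = 0.32

MODES = ("chains_only", "all_assemblies")


@dataclass(frozen=True)
class TimeSeriesRecord:
    """Simulated observables at one time point."""

    time: float                 # days
    mean_length_units: float    # toroid units per assembly
    mean_length_nm: float       # same, mapped to physical length
    active_fraction: float      # fraction of subunits in the slipped state
    cd_signal: float            # arbitrary units
    dls_diameter_nm: float      # intensity-weighted hydrodynamic diameter

    def __post_init__(self):
        if not 0.0 <= self.active_fraction <= 1.0 + 1e-9:
            raise ConfigurationError(
                f"active_fraction out of [0, 1]: {self.active_fraction}"
            )
        if self.mean_length_units < 1.0 - 1e-9:
            raise ConfigurationError(
                f"mean_length_units must be >= 1, got {self.mean_length_units}"
            )


def mean_chain_length(state: SystemState, mode: str = "chains_only") -> float:
    """Mean assembly size in toroid units.

    ``chains_only`` averages over helical chains (1.0 when there are none,
    i.e. only intact toroids are present); ``all_assemblies`` counts every
    free toroid as an assembly of length 1, which is what a micrograph
    count of all visible objects measures.
    """
    if mode not in MODES:
        raise ConfigurationError(f"mode must be one of {MODES}, got {mode!r}")
    if mode == "chains_only":
        if not state.chains:
            return 1.0
        return state.chain_units / len(state.chains)
    n_obj = state.n_free + len(state.chains)
    if n_obj == 0:
        return 1.0
    return state.total_units / n_obj


def cd_proxy(active_fraction: float, baseline: float = 0.0, amplitude: float = 1.0) -> float:
    """Affine CD intensity proxy: ``baseline + amplitude · active_fraction``.

    Intensive in system size, hence independent of concentration at fixed
    composition — the model image of the concentration-independent CD decay.
    """
    if amplitude < 0:
        raise ConfigurationError(f"amplitude must be >= 0, got {amplitude}")
    return baseline + amplitude * np.asarray(active_fraction)


def length_to_nm(n_units, geometry: ToroidGeometry | None = None):
    """Measured length of an assembly of ``n_units`` toroids, in nm.

    A single toroid reports its external diameter; a chain of n units forms
    n helical turns and reports ``n × pitch``.
    """
    g = geometry or ToroidGeometry()
    n = np.asarray(n_units)
    if np.any(n < 1):
        raise ConfigurationError("n_units must be >= 1")
    out = np.where(n == 1, g.external_diameter, n * g.pitch)
    return float(out) if np.isscalar(n_units) else out


def nm_to_length(length_nm, geometry: ToroidGeometry | None = None):
    """Inverse of :func:`length_to_nm` (units from measured length)."""
    g = geometry or ToroidGeometry()
    L = np.asarray(length_nm, dtype=float)
    out = np.where(np.isclose(L, g.external_diameter), 1.0, L / g.pitch)
    return float(out) if np.isscalar(length_nm) else out


def hydrodynamic_diameter(n_units, geometry: ToroidGeometry | None = None):
    """Hydrodynamic diameter (nm) of one assembly of ``n_units`` toroids.

    Single toroids use the sphere rule (external diameter).  Chains use the
    short rigid-rod approximation ``D_h = L / (ln(L/d) + 0.32)`` with
    ``L = n × pitch`` and ``d`` the helix external diameter.  Below the
    formula's turning point (L = d·e^0.68) the rod expression is not
    monotone, so short chains fall back to ``max(d, L)``, keeping the proxy
    continuous and nondecreasing in chain length.
    """
    g = geometry or ToroidGeometry()
    n = np.asarray(n_units, dtype=float)
    d = g.external_diameter
    L = n * g.pitch
    L_star = d * math.exp(1.0 - ROD_END_CORRECTION)
    with np.errstate(divide="ignore", invalid="ignore"):
        rod = L / (np.log(L / d) + ROD_END_CORRECTION)
    out = np.where(L >= L_star, rod, np.maximum(d, L))
    out = np.where(n == 1, d, out)
    return float(out) if np.isscalar(n_units) else out


def dls_proxy(state: SystemState, geometry: ToroidGeometry | None = None) -> float:
    """Intensity-weighted mean hydrodynamic diameter of the population (nm).

    Scattering weight of an assembly is taken proportional to its mass
    squared (``units²``), the simplest DLS-like intensity weighting.
    """
    g = geometry or ToroidGeometry()
    weights = []
    diams = []
    if state.n_free:
        weights.append(float(state.n_free))
        diams.append(g.external_diameter)
    if state.chains:
        ns = np.asarray(state.chains, dtype=float)
        weights.extend(ns**2)
        diams.extend(np.atleast_1d(hydrodynamic_diameter(ns, g)))
    if not weights:
        return g.external_diameter
    w = np.asarray(weights)
    return float(np.average(np.asarray(diams), weights=w))


def sample_cryotem(
    state: SystemState,
    n: int = 100,
    noise_sd_log: float = 0.1,
    rng: np.random.Generator | None = None,
    include_monomers: bool = True,
    geometry: ToroidGeometry | None = None,
) -> np.ndarray:
    """Simulate measuring ``n`` assembly lengths (nm) from a micrograph.

    Assemblies are drawn with probability proportional to their count
    (free toroids included by default, as short objects are visible in the
    micrographs), then multiplicative log-normal measurement noise of
    standard deviation ``noise_sd_log`` (log scale) is applied.
    """
    if n < 1:
        raise ConfigurationError(f"n must be >= 1, got {n}")
    if noise_sd_log < 0:
        raise ConfigurationError("noise_sd_log must be >= 0")
    g = geometry or ToroidGeometry()
    rng = rng or np.random.default_rng()
    units = list(state.chains)
    counts = [1.0] * len(units)
    if include_monomers and state.n_free:
        units.append(1)
        counts.append(float(state.n_free))
    if not units:
        raise ConfigurationError("state has no observable assemblies")
    p = np.asarray(counts) / np.sum(counts)
    picked = rng.choice(len(units), size=n, p=p)
    lengths = np.asarray([length_to_nm(units[i], g) for i in picked], dtype=float)
    if noise_sd_log > 0:
        lengths = lengths * np.exp(rng.normal(0.0, noise_sd_log, size=n))
    return lengths


def record_from_state(
    state: SystemState,
    geometry: ToroidGeometry | None = None,
    mode: str = "all_assemblies",
    cd_baseline: float = 0.0,
    cd_amplitude: float = 1.0,
) -> TimeSeriesRecord:
    """Bundle all observable proxies for one state snapshot."""
    g = geometry or ToroidGeometry()
    mlu = mean_chain_length(state, mode)
    if mode == "chains_only" and not state.chains:
        ml_nm = g.external_diameter
    elif mode == "chains_only":
        ml_nm = mlu * g.pitch
    else:
        n_obj = state.n_free + len(state.chains)
        ml_nm = (
            (state.n_free * g.external_diameter + state.chain_units * g.pitch) / n_obj
            if n_obj else g.external_diameter
        )
    af = state.active_fraction
    return TimeSeriesRecord(
        time=state.time,
        mean_length_units=mlu,
        mean_length_nm=ml_nm,
        active_fraction=af,
        cd_signal=float(cd_proxy(af, cd_baseline, cd_amplitude)),
        dls_diameter_nm=dls_proxy(state, g),
    )
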