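"""Helix and vesicle geometry.

A chain of n toroids forms a continuous helix of n one-turn spirals: the
helix external diameter equals the toroid's external diameter regardless of
length, the pitch defaults to the tube diameter (close-packed turns), and
the S enantiomer gives right-handed helices (positive centerline torsion),
the R enantiomer left-handed.  Racemic mixtures cannot open into a spiral
and therefore cannot polymerize: the builder refuses chirality 0.

A helix growing inside a spherical vesicle forces it into a spherocylinder
(cylinder with hemispherical caps) of total length equal to the rod length.
The default constraint conserves membrane area (lipid bilayers are nearly
inextensible while water permeates freely over days); a fixed-volume mode
is provided as an alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import ConfigurationError, InfeasibleShapeError
from .params import ToroidGeometry

__all__ = [
    "HelixModel", "VesicleShape",
    "build_helix", "handedness_of", "vesicle_shape", "vesicle_recovery",
]

POINTS_PER_TURN = 36


@dataclass(frozen=True)
class HelixModel:
    """A helical-chain centerline with chirality bookkeeping (lengths in nm)."""

    centerline: np.ndarray       # (N, 3) points
    n_turns: int
    handedness: int              # +1 right-handed, −1 left-handed
    external_diameter: float
    pitch: float

    @property
    def axial_length(self) -> float:
        return self.n_turns * self.pitch

    @property
    def contour_length(self) -> float:
        d = np.diff(self.centerline, axis=0)
        return float(np.sum(np.linalg.norm(d, axis=1)))

    def reflect(self) -> "HelixModel":
        """Mirror image through the xz-plane (flips handedness)."""
        pts = self.centerline.copy()
        pts[:, 1] *= -1.0
        return HelixModel(
            centerline=pts,
            n_turns=self.n_turns,
            handedness=-self.handedness,
            external_diameter=self.external_diameter,
            pitch=self.pitch,
        )

    def to_xyz(self, path, comment: str = "helix centerline") -> None:
        """Write the centerline as an XYZ point file (pseudo-atoms 'C')."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.centerline)}\n{comment}\n")
            for x, y, z in self.centerline:
                fh.write(f"C {x:.6f} {y:.6f} {z:.6f}\n")


def build_helix(geometry: ToroidGeometry, n_units: int,
                points_per_turn: int = POINTS_PER_TURN) -> HelixModel:
    """Concatenate ``n_units`` one-turn spirals into a continuous helix.

    The centerline winds at the toroid's centerline radius
    ``(external − tube diameter) / 2`` around the z axis, advancing one
    pitch per turn; chirality +1 (S) builds a right-handed helix.
    """
    if n_units < 1:
        raise ConfigurationError(f"n_units must be >= 1, got {n_units}")
    if geometry.chirality == 0:
        raise ConfigurationError(
            "racemic toroids cannot tilt in one direction, never open into a "
            "spiral, and are unable to polymerize: no helix can be built"
        )
    hand = geometry.chirality
    r = geometry.centerline_radius
    p = geometry.pitch
    theta = np.linspace(0.0, 2.0 * math.pi * n_units, n_units * points_per_turn + 1)
    pts = np.column_stack([
        r * np.cos(theta),
        hand * r * np.sin(theta),
        p * theta / (2.0 * math.pi),
    ])
    return HelixModel(
        centerline=pts,
        n_turns=n_units,
        handedness=hand,
        external_diameter=geometry.external_diameter,
        pitch=p,
    )


def handedness_of(helix: HelixModel | np.ndarray) -> int:
    """Sign of the centerline's mean discrete torsion (+1 = right-handed).

    Uses the triple product of consecutive difference vectors, which has
    the sign of the local torsion for a sampled smooth curve.
    """
    pts = helix.centerline if isinstance(helix, HelixModel) else np.asarray(helix)
    if len(pts) < 4:
        raise ConfigurationError("need at least 4 centerline points (>= 2 turns)")
    v = np.diff(pts, axis=0)
    triple = np.einsum("ij,ij->i", np.cross(v[:-2], v[1:-1]), v[2:])
    mean = float(np.mean(triple))
    if mean == 0.0:
        raise ConfigurationError("centerline is planar; handedness undefined")
    return 1 if mean > 0 else -1


@dataclass(frozen=True)
class VesicleShape:
    """Spherocylinder: a cylinder of length ``cylinder_length`` with two
    hemispherical caps of radius ``cap_radius`` (lengths nm)."""

    cap_radius: float
    cylinder_length: float

    def __post_init__(self):
        if self.cap_radius <= 0:
            raise ConfigurationError(f"cap_radius must be > 0, got {self.cap_radius}")
        if self.cylinder_length < -1e-9:
            raise ConfigurationError(
                f"cylinder_length must be >= 0, got {self.cylinder_length}"
            )

    @property
    def total_length(self) -> float:
        return self.cylinder_length + 2.0 * self.cap_radius

    @property
    def area(self) -> float:
        """Membrane area, exactly 4πr² + 2πr·L_c."""
        r = self.cap_radius
        return 4.0 * math.pi * r**2 + 2.0 * math.pi * r * self.cylinder_length

    @property
    def volume(self) -> float:
        r = self.cap_radius
        return (4.0 / 3.0) * math.pi * r**3 + math.pi * r**2 * self.cylinder_length

    @property
    def aspect_ratio(self) -> float:
        return self.total_length / (2.0 * self.cap_radius)

    def to_dict(self) -> dict:
        return {
            "cap_radius_nm": self.cap_radius,
            "cylinder_length_nm": self.cylinder_length,
            "total_length_nm": self.total_length,
            "area_nm2": self.area,
            "volume_nm3": self.volume,
            "aspect_ratio": self.aspect_ratio,
        }


def vesicle_shape(
    rod_length: float,
    sphere_diameter: float = 500.0,
    constraint: str = "fixed_area",
    min_radius: float = 6.0,
) -> VesicleShape:
    """Shape of a vesicle containing a rigid rod of ``rod_length`` nm.

    A rod shorter than the sphere diameter leaves the vesicle spherical.
    A longer rod stretches it into a spherocylinder of total length equal
    to the rod length, solved under conservation of membrane area
    (``fixed_area``, default: A₀ = π·sphere_diameter²) or of enclosed
    volume (``fixed_volume``).  The tube cannot be thinner than
    ``min_radius`` (half the helix external diameter); rods needing a
    thinner tube raise :class:`InfeasibleShapeError` reporting the maximum
    supportable length.
    """
    if rod_length < 0:
        raise ConfigurationError(f"rod_length must be >= 0, got {rod_length}")
    if sphere_diameter <= 0:
        raise ConfigurationError("sphere_diameter must be > 0")
    if constraint not in ("fixed_area", "fixed_volume"):
        raise ConfigurationError(f"unknown constraint {constraint!r}")
    R0 = sphere_diameter / 2.0
    if rod_length <= sphere_diameter:
        return VesicleShape(cap_radius=R0, cylinder_length=0.0)
    T = rod_length
    if constraint == "fixed_area":
        # 4πr² + 2πr(T − 2r) = 4πR0²  ⇒  2πrT = 4πR0²  ⇒  r = 2R0²/T
        r = 2.0 * R0**2 / T
        if r < min_radius:
            raise InfeasibleShapeError(
                f"rod of {T:.1f} nm needs tube radius {r:.2f} nm < minimum "
                f"{min_radius} nm; maximum supportable length is "
                f"{2.0 * R0**2 / min_radius:.1f} nm",
                max_length_nm=2.0 * R0**2 / min_radius,
            )
        return VesicleShape(cap_radius=r, cylinder_length=T - 2.0 * r)
    # fixed_volume: (4/3)πr³ + πr²(T − 2r) = (4/3)πR0³
    V0 = (4.0 / 3.0) * math.pi * R0**3

    def f(r):
        return (4.0 / 3.0) * math.pi * r**3 + math.pi * r**2 * (T - 2.0 * r) - V0

    # f is increasing in r on (0, T/2]; f(T/2) corresponds to the sphere of
    # radius T/2 > R0, so a root exists in (0, T/2)
    r = brentq(f, 1e-9, T / 2.0, xtol=1e-10)
    if r < min_radius:
        # solve max T at r = min_radius
        t_max = (V0 - (4.0 / 3.0) * math.pi * min_radius**3) / (math.pi * min_radius**2) \
            + 2.0 * min_radius
        raise InfeasibleShapeError(
            f"rod of {T:.1f} nm needs tube radius {r:.2f} nm < minimum "
            f"{min_radius} nm; maximum supportable length is {t_max:.1f} nm",
            max_length_nm=t_max,
        )
    return VesicleShape(cap_radius=r, cylinder_length=T - 2.0 * r)


def vesicle_recovery(shape: VesicleShape) -> VesicleShape:
    """Sphere the vesicle returns to once the rod depolymerizes (area kept)."""
    r = math.sqrt(shape.area / (4.0 * math.pi))
    return VesicleShape(cap_radius=r, cylinder_length=0.0)
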