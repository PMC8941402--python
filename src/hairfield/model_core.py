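"""Domain types, nondimensionalization and biological parameter calculators.

The model describes an array of charged filiform hairs (trichobothria,
cercal hairs) as inverted torsional pendulums.  Each hair carries its
charge at the tip and deflects in the plane under Coulomb torques from
its neighbours and from an external point charge, balanced by a linear
torsional spring.  All geometry is nondimensional: positions and lengths
are measured in units of the typical hair length ``L``, spring constants
in units of the typical spring constant ``S`` and charges in units of
the typical hair charge ``q``.  The single dimensionless group

    K = q^2 * k_e / (L * S)

(the electromechanical sensitivity) then controls the strength of every
electrostatic effect relative to the mechanical restoring torque.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import InvalidParameterError

__all__ = [
    "COULOMB_CONSTANT",
    "DEFAULT_THRESHOLD",
    "DEFAULT_SURFACE_CHARGE_DENSITY",
    "DimensionalParams",
    "HairSpec",
    "ArrayConfig",
    "PointCharge",
    "compute_K",
    "allometric_morphology",
    "hair_charge_upper_bound",
    "hair_spacing_from_density",
    "threshold_degrees",
    "nondimensionalize",
    "redimensionalize",
    "make_row_array",
]

#: Coulomb constant, N m^2 C^-2.
COULOMB_CONSTANT = 8.988e9

#: Default sensory deflection threshold, radians (~0.057 degrees); within
#: the range of neurally effective deflections reported for crickets and
#: spiders.
DEFAULT_THRESHOLD = 1e-3

#: Surface charge density at the limit of dielectric breakdown, C m^-2.
DEFAULT_SURFACE_CHARGE_DENSITY = 1e-4

# Allometric relations S(L) and d(L), SI units (L in meters).
_ALLOMETRY = {
    ("spider_MeD1", "spring"): (1.272e-5, 2.030),
    ("cricket_cercal", "spring"): (1.944e-6, 1.67),
    ("spider_MeD1", "diameter"): (6.343e-5, 0.3063),
    ("cricket_cercal", "diameter"): (8.34e-4, 0.67),
}


@dataclass(frozen=True)
class DimensionalParams:
    """Dimensional (SI) parameters of a typical hair.

    Attributes
    ----------
    hair_length : float
        Hair length L, meters.
    spring_constant : float
        Torsional spring constant S, kg m^2 s^-2.
    hair_charge : float
        Total hair charge q, coulombs (sign allowed).
    coulomb_constant : float
        Coulomb constant k_e, N m^2 C^-2; fixed by default.
    """

    hair_length: float
    spring_constant: float
    hair_charge: float
    coulomb_constant: float = COULOMB_CONSTANT

    def __post_init__(self):
        if not (self.hair_length > 0):
            raise InvalidParameterError("hair_length must be positive")
        if not (self.spring_constant > 0):
            raise InvalidParameterError("spring_constant must be positive")
        for name in ("hair_length", "spring_constant", "hair_charge", "coulomb_constant"):
            if not math.isfinite(getattr(self, name)):
                raise InvalidParameterError(f"{name} must be finite")


@dataclass(frozen=True)
class HairSpec:
    """One hair in nondimensional units (hair lengths, typical S and q)."""

    base_x: float
    base_y: float
    length: float = 1.0
    charge: float = 1.0
    spring: float = 1.0
    resting_angle: float = 0.0

    def __post_init__(self):
        if not (self.length > 0):
            raise InvalidParameterError("hair length must be positive")
        if not (self.spring > 0):
            raise InvalidParameterError("hair spring constant must be positive")
        for name in ("base_x", "base_y", "length", "charge", "spring", "resting_angle"):
            if not math.isfinite(getattr(self, name)):
                raise InvalidParameterError(f"{name} must be finite")


@dataclass(frozen=True)
class PointCharge:
    """External point charge, planar and immobile, nondimensional units."""

    x: float
    y: float
    magnitude: float = 1.0

    def __post_init__(self):
        for name in ("x", "y", "magnitude"):
            if not math.isfinite(getattr(self, name)):
                raise InvalidParameterError(f"{name} must be finite")


@dataclass(frozen=True)
class ArrayConfig:
    """A hair array plus the global coupling constant and sensory threshold.

    ``K`` is the electromechanical sensitivity (dimensionless, >= 0) and
    ``threshold`` the sensory deflection threshold theta_s in radians.
    The threshold is restricted to (0, 0.1] so the torsional oscillator
    stays in its linear small-deflection regime.
    """

    hairs: tuple[HairSpec, ...]
    K: float = 1.0
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self):
        hairs = tuple(self.hairs)
        object.__setattr__(self, "hairs", hairs)
        if len(hairs) < 1:
            raise InvalidParameterError("an array needs at least one hair")
        if not (self.K >= 0) or not math.isfinite(self.K):
            raise InvalidParameterError("K must be finite and >= 0")
        if not (0 < self.threshold <= 0.1):
            raise InvalidParameterError("threshold must lie in (0, 0.1] rad")
        bases = {(h.base_x, h.base_y) for h in hairs}
        if len(bases) != len(hairs):
            raise InvalidParameterError("hair base positions must be pairwise distinct")

    @property
    def n_hairs(self) -> int:
        return len(self.hairs)

    def arrays(self):
        """Per-hair parameter vectors (base_x, base_y, L, q, S, theta_0)."""
        h = self.hairs
        return (
            np.array([s.base_x for s in h]),
            np.array([s.base_y for s in h]),
            np.array([s.length for s in h]),
            np.array([s.charge for s in h]),
            np.array([s.spring for s in h]),
            np.array([s.resting_angle for s in h]),
        )

    def centroid(self) -> tuple[float, float]:
        """Centroid of the hair base positions ('middle of the array')."""
        return (
            float(np.mean([s.base_x for s in self.hairs])),
            float(np.mean([s.base_y for s in self.hairs])),
        )

    def single_hair(self, hair_id: int, resting_angle: float | None = None) -> "ArrayConfig":
        """Isolate one hair as its own (uncoupled) array.

        Optionally rotate its resting angle — used for coupled/uncoupled
        comparisons where the uncoupled hair is rested at the coupled
        equilibrium orientation.
        """
        spec = self.hairs[hair_id]
        if resting_angle is not None:
            spec = replace(spec, resting_angle=float(resting_angle))
        return ArrayConfig(hairs=(spec,), K=self.K, threshold=self.threshold)


def compute_K(params: DimensionalParams) -> float:
    """Electromechanical sensitivity K = q^2 k_e / (L S).

    K is the ratio of the electrical parameters of the hair system to its
    mechanical parameters; quadratic in the charge, inversely proportional
    to hair length and spring constant.
    """
    p = params
    return p.hair_charge**2 * p.coulomb_constant / (p.hair_length * p.spring_constant)


def allometric_morphology(L: float, species: str, quantity: str) -> float:
    """Evaluate an allometric relation for hair morphology.

    Parameters
    ----------
    L : float
        Hair length in meters (> 0).
    species : {"spider_MeD1", "cricket_cercal"}
        Spider MeD1 trichobothria or cricket cercal hairs.
    quantity : {"spring", "diameter"}
        Torsional spring constant (kg m^2 s^-2) or hair diameter (m).

    Returns
    -------
    float
        The SI value ``a * L**b`` of the published power law.
    """
    if not (L > 0) or not math.isfinite(L):
        raise InvalidParameterError("L must be positive and finite")
    try:
        a, b = _ALLOMETRY[(species, quantity)]
    except KeyError:
        raise InvalidParameterError(
            f"unknown (species, quantity) = ({species!r}, {quantity!r}); "
            f"expected species in {{spider_MeD1, cricket_cercal}} and "
            f"quantity in {{spring, diameter}}"
        ) from None
    return a * L**b


def hair_charge_upper_bound(
    d: float, L: float, sigma: float = DEFAULT_SURFACE_CHARGE_DENSITY
) -> float:
    """Upper bound on hair charge from total surface charge: q = pi d L sigma.

    ``d`` is the hair diameter (m), ``L`` the hair length (m) and ``sigma``
    the surface charge density (C m^-2), by default the dielectric-breakdown
    limit 1e-4.
    """
    if not (d > 0 and L > 0):
        raise InvalidParameterError("d and L must be positive")
    if sigma < 0:
        raise InvalidParameterError("sigma must be non-negative")
    return math.pi * d * L * sigma


def hair_spacing_from_density(density_per_mm2: float, L_mm: float = 1.0) -> float:
    """Nondimensional hair spacing implied by an areal hair density.

    For ``n`` hairs per square millimetre the one-dimensional spacing is
    ``1/sqrt(n)`` mm, expressed here in units of the hair length ``L_mm``
    (millimetres).
    """
    if not (density_per_mm2 > 0 and L_mm > 0):
        raise InvalidParameterError("density and hair length must be positive")
    return 1.0 / math.sqrt(density_per_mm2) / L_mm


def threshold_degrees(threshold_rad: float) -> float:
    """Sensory threshold expressed in degrees."""
    return math.degrees(threshold_rad)


def nondimensionalize(
    hairs: list[dict],
    L: float,
    S: float,
    q: float,
    threshold: float = DEFAULT_THRESHOLD,
) -> ArrayConfig:
    """Scale dimensional hairs by typical scales (L, S, q) into an ArrayConfig.

    ``hairs`` is a list of dicts with SI keys ``base_x, base_y, length,
    charge, spring`` and optional ``resting_angle`` (radians, unscaled).
    Positions and lengths are divided by ``L``, spring constants by ``S``
    and charges by ``q``; K is computed from the typical scales.
    """
    if not (L > 0 and S > 0 and q != 0):
        raise InvalidParameterError("typical scales L, S must be positive and q nonzero")
    specs = tuple(
        HairSpec(
            base_x=h["base_x"] / L,
            base_y=h["base_y"] / L,
            length=h["length"] / L,
            charge=h["charge"] / q,
            spring=h["spring"] / S,
            resting_angle=h.get("resting_angle", 0.0),
        )
        for h in hairs
    )
    K = compute_K(DimensionalParams(hair_length=L, spring_constant=S, hair_charge=q))
    return ArrayConfig(hairs=specs, K=K, threshold=threshold)


def redimensionalize(config: ArrayConfig, L: float, S: float, q: float) -> list[dict]:
    """Inverse of :func:`nondimensionalize` (angles are left untouched)."""
    if not (L > 0 and S > 0 and q != 0):
        raise InvalidParameterError("typical scales L, S must be positive and q nonzero")
    return [
        {
            "base_x": h.base_x * L,
            "base_y": h.base_y * L,
            "length": h.length * L,
            "charge": h.charge * q,
            "spring": h.spring * S,
            "resting_angle": h.resting_angle,
        }
        for h in config.hairs
    ]


def make_row_array(
    N: int,
    delta: float = 1.0,
    lengths: float | list[float] = 1.0,
    charges: float | list[float] = 1.0,
    springs: float | list[float] = 1.0,
    resting_angles: float | list[float] = 0.0,
    K: float = 1.0,
    threshold: float = DEFAULT_THRESHOLD,
) -> ArrayConfig:
    """Standard fixture: N hairs in a row along y = 0, bases delta apart.

    Bases sit at (0, 0), (delta, 0), ..., ((N-1) delta, 0).  Per-hair
    parameters accept either a scalar (broadcast) or a length-N list.
    """
    if N < 1:
        raise InvalidParameterError("N must be >= 1")
    if N >= 2 and not (delta > 0):
        raise InvalidParameterError("delta must be positive for N >= 2")

    def broadcast(v, name):
        if np.isscalar(v):
            return [float(v)] * N
        v = list(v)
        if len(v) != N:
            raise InvalidParameterError(f"{name} must be a scalar or length-{N} list")
        return [float(x) for x in v]

    Ls = broadcast(lengths, "lengths")
    qs = broadcast(charges, "charges")
    Ss = broadcast(springs, "springs")
    ths = broadcast(resting_angles, "resting_angles")
    specs = tuple(
        HairSpec(base_x=i * delta, base_y=0.0, length=Ls[i], charge=qs[i],
                 spring=Ss[i], resting_angle=ths[i])
        for i in range(N)
    )
    return ArrayConfig(hairs=specs, K=K, threshold=threshold)
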