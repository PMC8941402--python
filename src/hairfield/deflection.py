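"""Hair deflections caused by an external point charge.

Given a solved hair-array equilibrium, a fixed external point charge
perturbs every hair to a new angle; the sensory quantity is the
deflection from equilibrium, Delta theta_h = theta_h - theta_{h,e}.
``deflection_field`` evaluates this over a grid of candidate charge
locations — each cell is an independent quasi-static solve, batched
through the vectorized Newton core — producing the raw material for
sensitivity contours and coverage metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _solver
from .equilibrium import EquilibriumState, solve_equilibrium, RESIDUAL_TOL
from .exceptions import InvalidParameterError
from .model_core import ArrayConfig, PointCharge

__all__ = [
    "DeflectionResult",
    "FieldGrid",
    "solve_with_charge",
    "solve_charges",
    "deflection_field",
    "estimate_domain",
]

#: Grid cells closer than this (hair lengths) to an equilibrium tip are
#: masked: the Coulomb force diverges there and solutions are artefacts.
TIP_EXCLUSION_RADIUS = 1e-3


@dataclass(frozen=True)
class DeflectionResult:
    """Hair angles in the presence of a point charge.

    ``angles`` are absolute angles; ``delta_angles`` are deflections from
    the charge-free equilibrium, hair-wise.  ``valid`` mirrors solver
    convergence and non-singular geometry.
    """

    angles: np.ndarray
    delta_angles: np.ndarray
    valid: bool


@dataclass(frozen=True)
class FieldGrid:
    """Per-hair deflection-from-equilibrium over a grid of charge locations.

    ``values[h, j, i]`` is Delta theta of hair ``h`` for a charge at
    ``(x_coords[i], y_coords[j])``; ``mask[j, i]`` is True where the cell
    is valid (converged, outside tip-exclusion zones).  Masked cells are
    excluded from all downstream metrics.
    """

    x_coords: np.ndarray
    y_coords: np.ndarray
    values: np.ndarray
    charge_magnitude: float
    mask: np.ndarray
    equilibrium: EquilibriumState

    def __post_init__(self):
        if self.x_coords.size < 2 or self.y_coords.size < 2:
            raise InvalidParameterError("grid needs at least 2 points per axis")
        for ax in (self.x_coords, self.y_coords):
            if np.any(np.diff(ax) <= 0):
                raise InvalidParameterError("grid axes must be strictly increasing")
        N, ny, nx = self.values.shape
        if (ny, nx) != (self.y_coords.size, self.x_coords.size):
            raise InvalidParameterError("values shaped (N_hairs, len(y), len(x))")

    @property
    def cell_area(self) -> float:
        dx = float(np.mean(np.diff(self.x_coords)))
        dy = float(np.mean(np.diff(self.y_coords)))
        return dx * dy


def estimate_domain(config: ArrayConfig, charge_magnitude: float,
                    threshold: float | None = None, margin: float = 1.5):
    """Square grid bounds guaranteed to contain the far-field contour.

    In the far field an isolated hair deflects by about
    K q_h q_p / r^2, so the threshold contour reaches
    r* = sqrt(K q_h q_p / theta_s); the box half-width is ``margin`` times
    that, centered on the array centroid.  A zero K or charge magnitude
    falls back to a 10-hair-length box.
    """
    if threshold is None:
        threshold = config.threshold
    qmax = max(abs(h.charge) for h in config.hairs)
    strength = config.K * qmax * abs(charge_magnitude)
    cx, cy = config.centroid()
    if strength == 0:
        half = 10.0
    else:
        half = margin * float(np.sqrt(strength / threshold))
    return (cx - half, cx + half, cy - half, cy + half)


def solve_with_charge(config: ArrayConfig, equilibrium: EquilibriumState,
                      charge: PointCharge) -> DeflectionResult:
    """Hair angles with a point charge present, seeded from equilibrium."""
    if charge.magnitude == 0.0:
        return DeflectionResult(
            angles=equilibrium.angles.copy(),
            delta_angles=np.zeros_like(equilibrium.angles),
            valid=equilibrium.valid,
        )
    thetas, conv, res, _ = _solver.newton(
        config, equilibrium.angles[None, :],
        np.array([[charge.x, charge.y]]), charge.magnitude, tol=RESIDUAL_TOL,
    )
    return DeflectionResult(
        angles=thetas[0],
        delta_angles=thetas[0] - equilibrium.angles,
        valid=bool(conv[0]),
    )


def solve_charges(config: ArrayConfig, equilibrium: EquilibriumState,
                  points, charge_magnitude: float):
    """Batched point solves: deflections from equilibrium at many locations.

    Parameters
    ----------
    points : ndarray (M, 2)
        Candidate charge locations.
    charge_magnitude : float

    Returns
    -------
    delta : ndarray (M, N)
        Deflections from equilibrium per hair.
    valid : ndarray (M,) of bool
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    M = points.shape[0]
    init = np.broadcast_to(equilibrium.angles, (M, config.n_hairs)).copy()
    thetas, conv, _, _ = _solver.newton(
        config, init, points, charge_magnitude, tol=RESIDUAL_TOL
    )
    return thetas - equilibrium.angles, conv


def deflection_field(config: ArrayConfig, charge_magnitude: float,
                     bounds=None, nx: int = 401, ny: int = 401,
                     equilibrium: EquilibriumState | None = None) -> FieldGrid:
    """Deflection-from-equilibrium over a grid of candidate charge locations.

    Each cell is solved independently (vectorized Newton seeded at the
    charge-free equilibrium; unconverged cells are retried from converged
    neighbours, then masked).  Cells within ``TIP_EXCLUSION_RADIUS`` of an
    equilibrium tip are masked up front.
    """
    if nx < 2 or ny < 2:
        raise InvalidParameterError("grid must have at least 2x2 cells")
    if equilibrium is None:
        equilibrium = solve_equilibrium(config)
    if bounds is None:
        bounds = estimate_domain(config, charge_magnitude)
    x0, x1, y0, y1 = bounds
    if not (x1 > x0 and y1 > y0):
        raise InvalidParameterError("empty grid bounds")
    xs = np.linspace(x0, x1, nx)
    ys = np.linspace(y0, y1, ny)
    N = config.n_hairs

    XX, YY = np.meshgrid(xs, ys)
    pts = np.column_stack([XX.ravel(), YY.ravel()])
    M = pts.shape[0]

    near_tip = np.zeros(M, dtype=bool)
    for tip in equilibrium.tips:
        near_tip |= np.hypot(pts[:, 0] - tip[0], pts[:, 1] - tip[1]) < TIP_EXCLUSION_RADIUS

    delta = np.zeros((M, N))
    valid = np.zeros(M, dtype=bool)
    todo = ~near_tip
    if charge_magnitude == 0.0:
        valid[todo] = True
    else:
        d, conv = solve_charges(config, equilibrium, pts[todo], charge_magnitude)
        delta[todo] = d
        valid[todo] = conv
        # Retry failed cells seeded from the nearest converged neighbour
        # along the row (continuity of the solution branch).
        failed = todo & ~valid
        if np.any(failed):
            ok_idx = np.where(valid)[0]
            if ok_idx.size:
                fail_idx = np.where(failed)[0]
                # nearest converged cell in grid coordinates
                fi, fj = np.divmod(fail_idx, nx)
                oi, oj = np.divmod(ok_idx, nx)
                seeds = np.empty((fail_idx.size, N))
                for k in range(fail_idx.size):
                    d2 = (oi - fi[k]) ** 2 + (oj - fj[k]) ** 2
                    src = ok_idx[np.argmin(d2)]
                    seeds[k] = equilibrium.angles + delta[src]
                thetas, conv, _, _ = _solver.newton(
                    config, seeds, pts[fail_idx], charge_magnitude, tol=RESIDUAL_TOL
                )
                delta[fail_idx] = thetas - equilibrium.angles
                valid[fail_idx] = conv

    values = np.moveaxis(delta.reshape(ny, nx, N), 2, 0)
    mask = valid.reshape(ny, nx)
    return FieldGrid(
        x_coords=xs, y_coords=ys, values=values,
        charge_magnitude=float(charge_magnitude), mask=mask,
        equilibrium=equilibrium,
    )
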