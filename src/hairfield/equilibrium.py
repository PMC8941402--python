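"""Coupled hair equilibria: full solver, asymptotic limits, energy oracle.

With no external charge, mutual Coulomb repulsion between the charged
tips deflects every hair from its resting angle to an equilibrium angle
theta_{h,e} where elastic and electrostatic torques balance.  The solver
uses damped Newton iteration on the nondimensional angle balance with an
analytic Jacobian, initialized at the resting angles; failing that, it
continues geometrically in K (and then in spacing) from an easier
configuration, which selects the solution branch continuously connected
to the resting configuration.

Closed forms are provided for the two asymptotic regimes: near-flat
arrays with small equilibrium angles (explicit formula, valid when
K/delta^2 is small or hair-length differences dominate), and the
zero-spacing limit where all bases coincide and the equilibrium fan of
angles depends only on K and the per-hair parameters.  A total-energy
function serves as an independent oracle: equilibria are stationary
points of the elastic-plus-Coulomb energy.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq, root

from . import _solver
from .exceptions import InvalidParameterError, SingularGeometryError, SINGULAR_DISTANCE
from .model_core import ArrayConfig, HairSpec, PointCharge

__all__ = [
    "EquilibriumState",
    "tip_position",
    "equilibrium_residual",
    "solve_equilibrium",
    "total_energy",
    "energy_gradient_fd",
    "limiting_equilibrium_delta0",
    "symmetric_pair_limit",
    "small_angle_equilibrium",
]

#: Residual tolerance for converged equilibria.
RESIDUAL_TOL = 1e-10

#: Tip separations below this (hair lengths) flag a state as invalid.
MIN_TIP_SEPARATION = 1e-3


@dataclass(frozen=True)
class EquilibriumState:
    """Solved equilibrium of a hair array.

    Attributes
    ----------
    angles : ndarray, shape (N,)
        Equilibrium deflection angles theta_{h,e}, radians, measured
        clockwise from vertical (+y) toward +x.
    tips : ndarray, shape (N, 2)
        Nondimensional tip positions at equilibrium.
    residual_norm : float
        Max-norm of the angle-balance residual at the returned angles.
    iterations : int
        Newton steps used (including continuation stages).
    valid : bool
        True when converged, all |angles| < pi/2, and no two tips are
        closer than ``MIN_TIP_SEPARATION``.
    """

    angles: np.ndarray
    tips: np.ndarray
    residual_norm: float
    iterations: int
    valid: bool


def tip_position(hair: HairSpec, angle: float):
    """Tip of a hair at deflection ``angle``: base + L (sin, cos) of angle."""
    return (
        hair.base_x + hair.length * np.sin(angle),
        hair.base_y + hair.length * np.cos(angle),
    )


def equilibrium_residual(config: ArrayConfig, angles, charge: PointCharge | None = None):
    """Residual of the angle balance at the given angles.

    Zero iff the angles satisfy the coupled equilibrium equations (with
    the point-charge term included when ``charge`` is given).  Raises
    :class:`SingularGeometryError` when two tips, or a tip and the
    charge, nearly coincide.
    """
    angles = np.asarray(angles, dtype=float)
    charge_xy = None
    qp = 0.0
    if charge is not None:
        charge_xy = np.array([charge.x, charge.y])
        qp = charge.magnitude
    F, singular = _solver.residual(config, angles, charge_xy, qp)
    if np.any(singular):
        raise SingularGeometryError(
            f"tip/charge separation below {SINGULAR_DISTANCE} hair lengths"
        )
    return F[0]


def _state_from_solution(config, thetas, converged, res_norm, iterations):
    thetas = np.asarray(thetas, dtype=float).ravel()
    x, y = _solver.tips(config, thetas[None, :])
    tips = np.column_stack([x[0], y[0]])
    valid = bool(converged) and bool(np.all(np.abs(thetas) < np.pi / 2))
    if valid and config.n_hairs > 1:
        d = tips[:, None, :] - tips[None, :, :]
        r = np.sqrt(np.sum(d * d, axis=2))
        np.fill_diagonal(r, np.inf)
        valid = bool(np.min(r) >= MIN_TIP_SEPARATION)
    return EquilibriumState(
        angles=thetas,
        tips=tips,
        residual_norm=float(res_norm),
        iterations=int(iterations),
        valid=valid,
    )


def _scale_spacing(config: ArrayConfig, factor: float) -> ArrayConfig:
    """Scale all base positions about their centroid by ``factor``."""
    cx, cy = config.centroid()
    hairs = tuple(
        replace(h, base_x=cx + factor * (h.base_x - cx),
                base_y=cy + factor * (h.base_y - cy))
        for h in config.hairs
    )
    return dataclasses.replace(config, hairs=hairs)


def solve_equilibrium(config: ArrayConfig, theta_init=None,
                      charge: PointCharge | None = None) -> EquilibriumState:
    """Solve the coupled equilibrium equations of a hair array.

    A single hair has no interaction terms (and no external charge means
    no forcing), so its equilibrium is its resting angle exactly.  For
    coupled arrays, damped Newton from the resting angles; on failure,
    geometric continuation in K, then in spacing.  Non-convergence is
    reported through ``valid=False`` on the returned state, never as an
    exception.
    """
    N = config.n_hairs
    _, _, _, _, _, th0 = config.arrays()
    charge_xy = None
    qp = 0.0
    if charge is not None:
        charge_xy = np.array([[charge.x, charge.y]])
        qp = charge.magnitude

    if N == 1 and charge is None:
        return _state_from_solution(config, th0.copy(), True, 0.0, 0)

    init = th0.copy() if theta_init is None else np.asarray(theta_init, dtype=float)
    thetas, conv, res, iters = _solver.newton(
        config, init[None, :], charge_xy, qp, tol=RESIDUAL_TOL
    )
    if conv[0]:
        return _state_from_solution(config, thetas[0], True, res[0], iters)

    # Continuation in K: ramp up from a weakly coupled system.
    total_iters = iters
    guess = init.copy()
    ok = False
    for K_stage in np.geomspace(max(config.K, 1e-12) / 1024.0, config.K, 11):
        cfg_stage = dataclasses.replace(config, K=float(K_stage))
        thetas, conv, res, iters = _solver.newton(
            cfg_stage, guess[None, :], charge_xy, qp, tol=RESIDUAL_TOL
        )
        total_iters += iters
        if not conv[0]:
            ok = False
            break
        guess = thetas[0]
        ok = True
    if ok:
        return _state_from_solution(config, guess, True, res[0], total_iters)

    # Continuation in spacing: shrink from a 10x-spread copy of the array.
    guess = init.copy()
    ok = False
    for factor in np.geomspace(10.0, 1.0, 9):
        cfg_stage = _scale_spacing(config, float(factor))
        thetas, conv, res, iters = _solver.newton(
            cfg_stage, guess[None, :], charge_xy, qp, tol=RESIDUAL_TOL
        )
        total_iters += iters
        if not conv[0]:
            ok = False
            break
        guess = thetas[0]
        ok = True
    state = _state_from_solution(config, guess, ok, res[0], total_iters)
    if not ok:
        state = dataclasses.replace(state, valid=False)
    return state


def total_energy(config: ArrayConfig, angles, charge: PointCharge | None = None) -> float:
    """Total nondimensional energy: elastic + pairwise Coulomb (+ charge term).

    U = sum_h S_h (theta_h - theta_{h,0})^2 / 2
        + K sum_{h<i} q_h q_i / r_hi + K q_p sum_h q_h / r_hp

    Its partial derivative with respect to theta_h equals
    S_h * equilibrium_residual_h, making stationarity of U an independent
    check on any solved equilibrium.
    """
    angles = np.asarray(angles, dtype=float)
    bx, by, L, q, S, th0 = config.arrays()
    x = bx + L * np.sin(angles)
    y = by + L * np.cos(angles)
    U = 0.5 * np.sum(S * (angles - th0) ** 2)
    N = config.n_hairs
    if N > 1:
        dx = x[:, None] - x[None, :]
        dy = y[:, None] - y[None, :]
        r = np.sqrt(dx * dx + dy * dy)
        iu = np.triu_indices(N, k=1)
        if np.any(r[iu] < SINGULAR_DISTANCE):
            raise SingularGeometryError("coincident hair tips")
        U += config.K * np.sum(q[iu[0]] * q[iu[1]] / r[iu])
    if charge is not None and charge.magnitude != 0.0:
        rp = np.hypot(x - charge.x, y - charge.y)
        if np.any(rp < SINGULAR_DISTANCE):
            raise SingularGeometryError("point charge coincides with a hair tip")
        U += config.K * charge.magnitude * np.sum(q / rp)
    return float(U)


def energy_gradient_fd(config: ArrayConfig, angles,
                       charge: PointCharge | None = None, step: float = 1e-6):
    """Central finite-difference gradient of :func:`total_energy`."""
    angles = np.asarray(angles, dtype=float)
    grad = np.zeros_like(angles)
    for h in range(angles.size):
        up = angles.copy()
        dn = angles.copy()
        up[h] += step
        dn[h] -= step
        grad[h] = (total_energy(config, up, charge)
                   - total_energy(config, dn, charge)) / (2 * step)
    return grad


def _limit_residual(config: ArrayConfig, angles):
    """Residual of the zero-spacing equilibrium equations (bases coincident)."""
    _, _, L, q, S, th0 = config.arrays()
    dth = angles[:, None] - angles[None, :]
    r2 = L[:, None] ** 2 + L[None, :] ** 2 - 2 * L[:, None] * L[None, :] * np.cos(dth)
    np.fill_diagonal(r2, 1.0)
    r2 = np.maximum(r2, SINGULAR_DISTANCE**2)
    term = q[None, :] * L[None, :] * np.sin(dth) / r2**1.5
    np.fill_diagonal(term, 0.0)
    c = config.K * q * L / S
    return (angles - th0) - c * np.sum(term, axis=1)


def limiting_equilibrium_delta0(config: ArrayConfig):
    """Equilibrium angles in the limit of coincident hair bases.

    Solves the zero-spacing system in which inter-tip distances depend
    only on hair lengths and angle differences.  For identical hairs the
    trivial all-equal solution is unstable; the solver is seeded with a
    fan of angles (continuation in K on failure) and returns the fanned
    branch.  Returns ``(angles, valid)``.
    """
    N = config.n_hairs
    _, _, L, q, S, th0 = config.arrays()
    if config.K == 0:
        return th0.copy(), True
    if N == 1:
        return th0.copy(), True

    # Fan seed, ordered by base x so neighbours repel outward; for a
    # symmetric pair this is the antisymmetric branch.
    order = np.argsort(np.argsort([h.base_x for h in config.hairs], kind="stable"))
    fan = np.linspace(-1.0, 1.0, N)[order]
    if N == 2 and np.allclose(L, L[0]) and np.allclose(q, q[0]) and np.allclose(S, S[0]):
        amp = symmetric_pair_limit(config.K, L[0], S[0], q[0])
    else:
        amp = min(0.5, 0.3 * np.sqrt(config.K))
    guess = th0 + amp * fan

    for K_stage in [config.K] if config.K <= 1 else np.geomspace(1.0, config.K, 6):
        cfg = dataclasses.replace(config, K=float(K_stage))
        sol = root(lambda a: _limit_residual(cfg, a), guess, method="hybr",
                   options={"xtol": 1e-13})
        if sol.success:
            guess = sol.x
    final = np.max(np.abs(_limit_residual(config, guess)))
    return guess, bool(final <= 1e-8)


def symmetric_pair_limit(K: float, length: float = 1.0, spring: float = 1.0,
                         charge: float = 1.0) -> float:
    """Zero-spacing equilibrium deflection of two identical hairs.

    Solves  theta = (q^2 / (S L)) K cos(theta) / (4 sin^2 theta)  for the
    unique root in (0, pi/2); this is the maximum equilibrium deflection
    the pair can reach as spacing shrinks.  Returns 0 for K = 0.
    """
    if K < 0:
        raise InvalidParameterError("K must be >= 0")
    if K == 0:
        return 0.0
    a = charge**2 / (spring * length) * K

    def f(th):
        return 4.0 * th * np.sin(th) ** 2 - a * np.cos(th)

    return float(brentq(f, 1e-15, np.pi / 2 - 1e-15, xtol=1e-12, rtol=8.9e-16))


def small_angle_equilibrium(config: ArrayConfig, delta: float):
    """Explicit small-angle equilibrium for near-flat arrays.

    Valid when equilibrium angles are small (K/delta^2 small, or length
    differences dominating the inter-tip distance).  ``delta`` is the
    spacing scale: base coordinates are measured in units of delta, and
    length differences enter the tip separations as (L_h - L_i)/delta.
    """
    if not (delta > 0):
        raise InvalidParameterError("delta must be positive")
    bx, by, L, q, S, th0 = config.arrays()
    xs = bx / delta
    ys = by / delta
    dxs = xs[:, None] - xs[None, :]
    dys = ys[:, None] - ys[None, :] + (L[:, None] - L[None, :]) / delta
    r2 = dxs**2 + dys**2
    np.fill_diagonal(r2, 1.0)
    term = q[None, :] * dxs / r2**1.5
    np.fill_diagonal(term, 0.0)
    c = L * q / S * config.K / delta**2
    return th0 + c * np.sum(term, axis=1)
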