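"""Inverse problem: locate a point charge from observed hair deflections.

Each hair's deflection from equilibrium constrains the charge to lie on
one iso-deflection curve; two hairs intersect two curves (a discrete set
of candidate points per assumed magnitude, tracing a one-dimensional
ambiguity curve when the magnitude is unknown); three or more hairs
generically pin down both location and magnitude.  The general solver is
nonlinear least squares on the forward model with seeded multi-start;
the two-hair contour-intersection construction is provided separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from . import _solver
from .deflection import solve_charges
from .equilibrium import solve_equilibrium
from .exceptions import InvalidParameterError
from .model_core import ArrayConfig

__all__ = ["ChargeEstimate", "localize_charge", "candidate_locus_two_hairs"]

#: Candidate solutions closer than this (hair lengths) are merged.
DEDUP_DISTANCE = 1e-4


@dataclass(frozen=True)
class ChargeEstimate:
    """One candidate point-charge solution.

    ``magnitude`` is None when the magnitude was known (not estimated).
    ``residual`` is the root-mean-square angle misfit in radians;
    ``multiplicity`` counts the distinct candidates found in the same run
    (symmetric arrays yield mirror pairs).
    """

    x: float
    y: float
    magnitude: float | None
    residual: float
    multiplicity: int


def _ring_starts(config, observed, qp_nominal, n_starts, rng):
    """Initial guesses on rings around the array centroid.

    Ring radii bracket the far-field distance implied by the observed
    deflection magnitudes, |dtheta| ~ K q_h q_p / r^2.
    """
    cx, cy = config.centroid()
    scale = np.median(np.abs(observed))
    qmax = max(abs(h.charge) for h in config.hairs)
    if scale > 0 and config.K * qmax * abs(qp_nominal) > 0:
        r_est = np.sqrt(config.K * qmax * abs(qp_nominal) / scale)
    else:
        r_est = 10.0
    n_rings = 4
    per_ring = max(1, n_starts // n_rings)
    radii = r_est * np.array([0.4, 1.0, 2.0, 4.0])
    starts = []
    for r in radii:
        phis = np.linspace(0, 2 * np.pi, per_ring, endpoint=False)
        phis = phis + rng.uniform(0, 2 * np.pi / per_ring)
        for phi in phis:
            starts.append((cx + r * np.sin(phi), cy + r * np.cos(phi)))
    return starts[:n_starts], r_est


def localize_charge(config: ArrayConfig, observed_angles, known_magnitude=None,
                    seed: int = 0, n_starts: int = 32,
                    absolute_angles: bool = False,
                    max_residual: float = 1e-6):
    """Infer point-charge location (and magnitude) from hair deflections.

    Parameters
    ----------
    observed_angles : array-like, shape (N,)
        Observed deflections from equilibrium (radians); pass
        ``absolute_angles=True`` to supply absolute angles instead.
    known_magnitude : float, optional
        If given, only (x, y) are estimated; otherwise magnitude too.
    seed : int
        Seeds the multi-start ring jitter (reproducible).
    max_residual : float
        Runs whose best RMS misfit exceeds this are discarded; with no
        survivors an empty list is returned.  Raise it when the
        observations are noisy.

    Returns
    -------
    list of ChargeEstimate
        Deduplicated local minima sorted by residual.
    """
    if config.n_hairs < 2:
        raise InvalidParameterError("localization needs at least 2 hairs")
    observed = np.asarray(observed_angles, dtype=float)
    if observed.shape != (config.n_hairs,):
        raise InvalidParameterError("one observed angle per hair required")
    equilibrium = solve_equilibrium(config)
    if absolute_angles:
        observed = observed - equilibrium.angles

    rng = np.random.default_rng(seed)
    estimate_qp = known_magnitude is None
    qp_nominal = 1.0 if estimate_qp else float(known_magnitude)
    starts, r_est = _ring_starts(config, observed, qp_nominal, n_starts, rng)

    def _solve_at(params):
        x, y = params[0], params[1]
        qp = params[2] if estimate_qp else qp_nominal
        pt = np.array([[x, y]])
        delta, ok = solve_charges(config, equilibrium, pt, qp)
        return pt, qp, delta[0], bool(ok[0])

    def misfit(params):
        _, _, delta, ok = _solve_at(params)
        if not ok:
            return np.full(config.n_hairs, 1e3)
        return delta - observed

    def misfit_jac(params):
        """Implicit differentiation: dtheta/dp = -J_theta^{-1} dF/dp."""
        pt, qp, delta, ok = _solve_at(params)
        n_par = 3 if estimate_qp else 2
        if not ok:
            return np.zeros((config.n_hairs, n_par))
        thetas = (equilibrium.angles + delta)[None, :]
        _, J, _ = _solver.residual_and_jac(config, thetas, pt, qp)
        dfx, dfy, dfq = _solver.charge_partials(config, thetas, pt, qp)
        rhs = [dfx[0], dfy[0], dfq[0]] if estimate_qp else [dfx[0], dfy[0]]
        return -np.linalg.solve(J[0], np.column_stack(rhs))

    scale = np.median(np.abs(observed))
    found = []
    for (x0, y0) in starts:
        if estimate_qp:
            r0 = np.hypot(x0 - config.centroid()[0], y0 - config.centroid()[1])
            qp0 = scale * max(r0, 1.0) ** 2 / max(config.K, 1e-12)
            p0 = [x0, y0, qp0]
        else:
            p0 = [x0, y0]
        try:
            sol = least_squares(misfit, p0, jac=misfit_jac, method="trf",
                                xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:
            continue
        rms = float(np.sqrt(np.mean(sol.fun**2)))
        found.append((sol.x, rms))

    if not found:
        return []
    keep = [f for f in found if f[1] <= max(max_residual, 1e-8)]
    if not keep:
        return []

    # Deduplicate by position.
    unique = []
    for params, rms in sorted(keep, key=lambda f: f[1]):
        if any(np.hypot(params[0] - u[0][0], params[1] - u[0][1]) < DEDUP_DISTANCE
               for u in unique):
            continue
        unique.append((params, rms))

    mult = len(unique)
    return [
        ChargeEstimate(
            x=float(p[0]), y=float(p[1]),
            magnitude=float(p[2]) if estimate_qp else None,
            residual=rms, multiplicity=mult,
        )
        for p, rms in unique
    ]


def candidate_locus_two_hairs(config: ArrayConfig, observed_angles,
                              magnitudes, seed: int = 0,
                              max_residual: float = 1e-8):
    """Two-hair ambiguity curve: one locus point per trial magnitude.

    For each trial magnitude the two iso-deflection curves
    {dtheta_1 = obs_1} and {dtheta_2 = obs_2} are intersected (least
    squares over position only); successive magnitudes are seeded from
    the previous solution, tracing the continuous ambiguity curve of the
    unknown-magnitude problem.  Magnitudes whose curves do not intersect
    are skipped with a warning.

    Returns a list of :class:`ChargeEstimate` with the trial magnitude
    recorded on each point.
    """
    if config.n_hairs != 2:
        raise InvalidParameterError("the locus construction is for exactly 2 hairs")
    observed = np.asarray(observed_angles, dtype=float)
    base_line = float(np.mean([h.base_y for h in config.hairs]))
    points = []
    prev = None
    for qp in magnitudes:
        ests = localize_charge(config, observed, known_magnitude=qp, seed=seed,
                               n_starts=16, max_residual=max_residual)
        if prev is not None and ests:
            # prefer the intersection continuous with the previous magnitude
            ests = sorted(ests, key=lambda e: np.hypot(e.x - prev[0], e.y - prev[1]))
        elif ests:
            # first magnitude: prefer the upper half-plane (the sensing
            # side of the substrate), then smaller residual
            ests = sorted(ests, key=lambda e: (e.y <= base_line, e.residual))
        if not ests:
            warnings.warn(f"no contour intersection for trial magnitude {qp}",
                          stacklevel=2)
            continue
        best = ests[0]
        prev = (best.x, best.y)
        points.append(ChargeEstimate(x=best.x, y=best.y, magnitude=float(qp),
                                     residual=best.residual,
                                     multiplicity=best.multiplicity))
    return points
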