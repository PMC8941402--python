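"""Vectorized residual/Jacobian assembly and damped Newton iteration.

The nondimensional angle balance for hair h is

    theta_h - theta_{h,0} = (K q_h L_h / S_h) * [ point-charge term
                              + sum_{i != h} inter-hair term_i ]

where each Coulomb term has the form

    q_src * ((x_h - x_src) cos(theta_h) - (y_h - y_src) sin(theta_h)) / r^3

with the tip positions x_h = x_{h,0} + L_h sin(theta_h),
y_h = y_{h,0} + L_h cos(theta_h).  The residual is the left-hand side
minus the right-hand side; it equals (1/S_h) dU/dtheta_h for the total
energy U (elastic + pairwise Coulomb), which the tests exploit as an
independent oracle.

Everything here is batched: ``thetas`` has shape (M, N) for M independent
scenarios (e.g. grid cells of candidate point-charge positions) over the
same N-hair array.  The Jacobian is assembled analytically and the (N x N)
systems are solved with one batched ``numpy.linalg.solve`` call.
"""

from __future__ import annotations

import numpy as np

from .exceptions import SINGULAR_DISTANCE

__all__ = ["tips", "residual", "residual_and_jac", "newton"]

#: Hard bound on |theta| during iteration; equilibria are physically
#: limited to a maximum of pi/2.
_THETA_CAP = np.pi / 2 * 0.9999


def tips(config, thetas):
    """Tip positions for batched angles; returns (x, y) with thetas' shape."""
    bx, by, L, _, _, _ = config.arrays()
    x = bx + L * np.sin(thetas)
    y = by + L * np.cos(thetas)
    return x, y


def _coulomb_terms(config, thetas, charge_xy, qp):
    """Shared geometry for residual and Jacobian.

    Returns a dict of intermediate arrays; ``thetas`` must be (M, N).
    """
    bx, by, L, q, S, th0 = config.arrays()
    sin_t = np.sin(thetas)
    cos_t = np.cos(thetas)
    x = bx + L * sin_t  # (M, N)
    y = by + L * cos_t

    out = {"sin": sin_t, "cos": cos_t, "x": x, "y": y}

    N = thetas.shape[-1]
    singular = np.zeros(thetas.shape[0], dtype=bool)

    if N > 1:
        dx = x[:, :, None] - x[:, None, :]  # (M, N, N), axis 1 = h, axis 2 = i
        dy = y[:, :, None] - y[:, None, :]
        r2 = dx * dx + dy * dy
        eye = np.eye(N, dtype=bool)
        r2 = np.where(eye, 1.0, r2)  # keep diagonal finite; excluded below
        singular |= np.any(r2 < SINGULAR_DISTANCE**2, axis=(1, 2))
        r2 = np.maximum(r2, SINGULAR_DISTANCE**2)
        inv_r3 = r2 ** -1.5
        inv_r3 = np.where(eye, 0.0, inv_r3)
        out.update(dx=dx, dy=dy, inv_r3=inv_r3, r2=r2)

    if charge_xy is not None and qp != 0.0:
        xp = charge_xy[..., 0][:, None]
        yp = charge_xy[..., 1][:, None]
        dxp = x - xp  # (M, N)
        dyp = y - yp
        rp2 = dxp * dxp + dyp * dyp
        singular |= np.any(rp2 < SINGULAR_DISTANCE**2, axis=1)
        rp2 = np.maximum(rp2, SINGULAR_DISTANCE**2)
        out.update(dxp=dxp, dyp=dyp, inv_rp3=rp2 ** -1.5)

    out["singular"] = singular
    return out


def residual(config, thetas, charge_xy=None, qp=0.0):
    """Batched residual of the angle balance.

    Parameters
    ----------
    config : ArrayConfig
    thetas : ndarray, shape (M, N) or (N,)
    charge_xy : ndarray, shape (M, 2) or (2,), optional
    qp : float
        Nondimensional point-charge magnitude.

    Returns
    -------
    F : ndarray, same shape as ``thetas``
    singular : ndarray of bool, shape (M,)
    """
    thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
    if charge_xy is not None:
        charge_xy = np.atleast_2d(np.asarray(charge_xy, dtype=float))
    bx, by, L, q, S, th0 = config.arrays()
    g = _coulomb_terms(config, thetas, charge_xy, qp)
    c = config.K * q * L / S  # (N,)

    rhs = np.zeros_like(thetas)
    if thetas.shape[-1] > 1:
        # A_hi = dx cos(theta_h) - dy sin(theta_h); sum over sources i
        A = g["dx"] * g["cos"][:, :, None] - g["dy"] * g["sin"][:, :, None]
        rhs += np.einsum("mhi,i->mh", A * g["inv_r3"], q)
    if charge_xy is not None and qp != 0.0:
        Ap = g["dxp"] * g["cos"] - g["dyp"] * g["sin"]
        rhs += qp * Ap * g["inv_rp3"]

    F = (thetas - th0) - c * rhs
    return F, g["singular"]


def residual_and_jac(config, thetas, charge_xy=None, qp=0.0):
    """Residual plus analytic Jacobian dF_h/dtheta_j, batched.

    Returns ``(F, J, singular)`` with ``J`` of shape (M, N, N).
    """
    thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
    if charge_xy is not None:
        charge_xy = np.atleast_2d(np.asarray(charge_xy, dtype=float))
    bx, by, L, q, S, th0 = config.arrays()
    M, N = thetas.shape
    g = _coulomb_terms(config, thetas, charge_xy, qp)
    c = config.K * q * L / S
    sin_t, cos_t = g["sin"], g["cos"]

    rhs = np.zeros_like(thetas)
    # d(rhs_h)/dtheta_h and d(rhs_h)/dtheta_i
    d_rhs_diag = np.zeros_like(thetas)
    J_off = np.zeros((M, N, N))

    if N > 1:
        dx, dy, inv_r3, r2 = g["dx"], g["dy"], g["inv_r3"], g["r2"]
        A = dx * cos_t[:, :, None] - dy * sin_t[:, :, None]  # (M, N, N)
        inv_r5 = inv_r3 / r2
        qi = q[None, None, :]
        rhs += np.sum(qi * A * inv_r3, axis=2)
        # dA/dtheta_h = L_h - dx sin(theta_h) - dy cos(theta_h)
        dA_dh = (L[None, :, None]
                 - dx * sin_t[:, :, None] - dy * cos_t[:, :, None])
        # dr/dtheta_h = L_h A / r  =>  d(1/r^3)/dtheta_h = -3 L_h A / r^5
        d_dh = qi * (dA_dh * inv_r3 - 3.0 * L[None, :, None] * A * A * inv_r5)
        d_rhs_diag += np.sum(d_dh, axis=2)
        # source-side derivative: dA/dtheta_i = -L_i cos(theta_h - theta_i)
        dth = thetas[:, :, None] - thetas[:, None, :]
        dA_di = -L[None, None, :] * np.cos(dth)
        # r dr/dtheta_i = L_i (-dx cos(theta_i) + dy sin(theta_i))
        rdr_di = L[None, None, :] * (-dx * cos_t[:, None, :] + dy * sin_t[:, None, :])
        d_di = qi * (dA_di * inv_r3 - 3.0 * A * rdr_di * inv_r5)
        J_off = -c[None, :, None] * d_di
        J_off[:, np.arange(N), np.arange(N)] = 0.0

    if charge_xy is not None and qp != 0.0:
        dxp, dyp, inv_rp3 = g["dxp"], g["dyp"], g["inv_rp3"]
        Ap = dxp * cos_t - dyp * sin_t
        rhs += qp * Ap * inv_rp3
        dAp = L[None, :] - dxp * sin_t - dyp * cos_t
        inv_rp5 = inv_rp3 ** (5.0 / 3.0)
        d_rhs_diag += qp * (dAp * inv_rp3 - 3.0 * L[None, :] * Ap * Ap * inv_rp5)

    F = (thetas - th0) - c * rhs
    J = J_off
    J[:, np.arange(N), np.arange(N)] = 1.0 - c * d_rhs_diag
    return F, J, g["singular"]


def charge_partials(config, thetas, charge_xy, qp):
    """Partials of the residual w.r.t. the point-charge parameters.

    Returns ``(dF_dxp, dF_dyp, dF_dqp)``, each of shape (M, N).  Used for
    implicit differentiation of the solved angles in the inverse problem:
    d(theta)/dp = -J^{-1} dF/dp along the solution manifold F = 0.
    """
    thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
    charge_xy = np.atleast_2d(np.asarray(charge_xy, dtype=float))
    bx, by, L, q, S, th0 = config.arrays()
    g = _coulomb_terms(config, thetas, charge_xy, qp if qp != 0 else 1.0)
    c = config.K * q * L / S
    sin_t, cos_t = g["sin"], g["cos"]
    dxp, dyp, inv_rp3 = g["dxp"], g["dyp"], g["inv_rp3"]
    Ap = dxp * cos_t - dyp * sin_t
    inv_rp5 = inv_rp3 ** (5.0 / 3.0)
    # term = qp * Ap / rp^3; F = ... - c * term
    dterm_dxp = qp * (-cos_t * inv_rp3 + 3.0 * Ap * dxp * inv_rp5)
    dterm_dyp = qp * (sin_t * inv_rp3 + 3.0 * Ap * dyp * inv_rp5)
    dterm_dqp = Ap * inv_rp3
    return -c * dterm_dxp, -c * dterm_dyp, -c * dterm_dqp


def newton(config, theta_init, charge_xy=None, qp=0.0,
           tol=1e-10, max_iter=200):
    """Damped (backtracking) Newton iteration, batched over scenarios.

    Parameters
    ----------
    theta_init : ndarray (M, N)
        Initial angles per scenario.
    charge_xy : ndarray (M, 2), optional
        Point-charge position per scenario (None for the bare array).
    qp : float
        Point-charge magnitude.
    tol : float
        Convergence threshold on max |residual| per scenario.

    Returns
    -------
    thetas : ndarray (M, N)
    converged : ndarray (M,) of bool
    res_norm : ndarray (M,) of float
    iterations : int
        Newton steps taken (max over the batch).
    """
    thetas = np.array(np.atleast_2d(theta_init), dtype=float)
    M, N = thetas.shape
    if charge_xy is not None:
        charge_xy = np.atleast_2d(np.asarray(charge_xy, dtype=float))

    singular_ever = np.zeros(M, dtype=bool)
    stalled = np.zeros(M, dtype=bool)
    res_norm = np.full(M, np.inf)
    iterations = 0

    F, sing = residual(config, thetas, charge_xy, qp)
    singular_ever |= sing
    res_norm = np.max(np.abs(F), axis=1)

    for it in range(max_iter):
        idx = np.where((res_norm > tol) & ~singular_ever & ~stalled)[0]
        if idx.size == 0:
            break
        iterations = it + 1

        th_a = thetas[idx]
        ch_a = charge_xy[idx] if charge_xy is not None else None
        Fa, Ja, sing_a = residual_and_jac(config, th_a, ch_a, qp)
        singular_ever[idx] |= sing_a
        # Guard near-singular Jacobians with a tiny Tikhonov bump.
        try:
            step = np.linalg.solve(Ja, Fa[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.linalg.solve(Ja + 1e-12 * np.eye(N), Fa[..., None])[..., 0]

        # Backtracking line search, vectorized over the active subset:
        # halve alpha where the residual norm failed to decrease.
        norm_a = res_norm[idx]
        alpha = np.ones(idx.size)
        best = th_a.copy()
        best_norm = norm_a.copy()
        live = np.ones(idx.size, dtype=bool)
        for _ in range(12):
            trial = np.clip(th_a - (alpha * live)[:, None] * step,
                            -_THETA_CAP, _THETA_CAP)
            Ft, sing_t = residual(config, trial, ch_a, qp)
            nt = np.max(np.abs(Ft), axis=1)
            nt = np.where(sing_t, np.inf, nt)
            improved = live & (nt < best_norm)
            best[improved] = trial[improved]
            best_norm[improved] = nt[improved]
            live = live & (nt >= norm_a)
            if not np.any(live):
                break
            alpha = np.where(live, alpha * 0.5, alpha)
        # Scenarios where even the damped step made no progress: stop them.
        stalled[idx[best_norm >= norm_a]] = True
        thetas[idx] = best
        res_norm[idx] = best_norm

    converged = (res_norm <= tol) & ~singular_ever
    return thetas, converged, res_norm, iterations
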