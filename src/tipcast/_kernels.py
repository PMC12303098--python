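"""Numba-compiled numerical kernels.

Everything here is deliberately free of Python objects: polynomial vector
fields are passed as coefficient arrays, named benchmark systems as jitted
``field(state, mu, out)`` / ``jac(state, mu, out)`` callbacks.  The drivers
implement plain Euler (deterministic paths) and Euler-Maruyama (pre-drawn
per-step noise increments) with a linear parameter ramp, the equilibrium
settling test, Newton correction and pseudo-arclength continuation for
two-dimensional polynomial systems.

The recovery rate lambda is the maximal real part of the Jacobian
eigenvalues evaluated *along the trajectory*; for 2x2 Jacobians a closed
form is used, larger systems go through ``np.linalg.eigvals``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# status codes shared by the drivers
OK = 0
DIVERGED = 1
NOT_CONVERGED = 2
TRUNCATED = 3


# ---------------------------------------------------------------------------
# polynomial field on the monomial basis (1, x, y, x2, xy, y2, x3, x2y, xy2, y3)
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _monomials(x, y, p):
    p[0] = 1.0
    p[1] = x
    p[2] = y
    p[3] = x * x
    p[4] = x * y
    p[5] = y * y
    p[6] = x * x * x
    p[7] = x * x * y
    p[8] = x * y * y
    p[9] = y * y * y


@njit(cache=True)
def poly_rhs(a, b, x, y):
    p = np.empty(10)
    _monomials(x, y, p)
    fx = 0.0
    fy = 0.0
    for i in range(10):
        fx += a[i] * p[i]
        fy += b[i] * p[i]
    return fx, fy


@njit(cache=True)
def poly_jac(a, b, x, y):
    # d p_i / dx and d p_i / dy on the fixed monomial ordering
    dpx = np.empty(10)
    dpy = np.empty(10)
    dpx[0] = 0.0; dpx[1] = 1.0; dpx[2] = 0.0
    dpx[3] = 2.0 * x; dpx[4] = y; dpx[5] = 0.0
    dpx[6] = 3.0 * x * x; dpx[7] = 2.0 * x * y; dpx[8] = y * y; dpx[9] = 0.0
    dpy[0] = 0.0; dpy[1] = 0.0; dpy[2] = 1.0
    dpy[3] = 0.0; dpy[4] = x; dpy[5] = 2.0 * y
    dpy[6] = 0.0; dpy[7] = x * x; dpy[8] = 2.0 * x * y; dpy[9] = 3.0 * y * y
    j11 = 0.0; j12 = 0.0; j21 = 0.0; j22 = 0.0
    for i in range(10):
        j11 += a[i] * dpx[i]
        j12 += a[i] * dpy[i]
        j21 += b[i] * dpx[i]
        j22 += b[i] * dpy[i]
    return j11, j12, j21, j22


@njit(cache=True, inline="always")
def eig2(j11, j12, j21, j22):
    """Eigenvalues of a 2x2 matrix as (re1, im1, re2, im2), re1 >= re2."""
    tr = j11 + j22
    det = j11 * j22 - j12 * j21
    disc = tr * tr - 4.0 * det
    if disc >= 0.0:
        s = np.sqrt(disc)
        return 0.5 * (tr + s), 0.0, 0.5 * (tr - s), 0.0
    s = np.sqrt(-disc)
    return 0.5 * tr, 0.5 * s, 0.5 * tr, -0.5 * s


@njit(cache=True)
def poly_lambda(a, b, x, y):
    j11, j12, j21, j22 = poly_jac(a, b, x, y)
    re1, _, re2, _ = eig2(j11, j12, j21, j22)
    return max(re1, re2)


@njit(cache=True, inline="always")
def _set_coeff(a, b, vidx, val):
    if vidx < 10:
        a[vidx] = val
    else:
        b[vidx - 10] = val


# ---------------------------------------------------------------------------
# settling to equilibrium (forward Euler, ring-buffer convergence test)
# ---------------------------------------------------------------------------

@njit(cache=True)
def settle_poly(a, b, x0, y0, dt, n_steps, tol, bound):
    """Integrate until the final 10 states differ by < tol coordinate-wise."""
    x = x0
    y = y0
    hx = np.empty(10)
    hy = np.empty(10)
    for i in range(n_steps):
        fx, fy = poly_rhs(a, b, x, y)
        x += fx * dt
        y += fy * dt
        if np.abs(x) > bound or np.abs(y) > bound or not (np.isfinite(x) and np.isfinite(y)):
            return x, y, DIVERGED
        hx[i % 10] = x
        hy[i % 10] = y
    span = max(hx.max() - hx.min(), hy.max() - hy.min())
    if span < tol:
        return x, y, OK
    return x, y, NOT_CONVERGED


@njit
def settle_named(field, s0, mu, dt, n_steps, tol, bound):
    dim = s0.shape[0]
    s = s0.copy()
    out = np.empty(dim)
    hist = np.empty((10, dim))
    for i in range(n_steps):
        field(s, mu, out)
        for d in range(dim):
            s[d] += out[d] * dt
            if np.abs(s[d]) > bound or not np.isfinite(s[d]):
                return s, DIVERGED
        hist[i % 10] = s
    span = 0.0
    for d in range(dim):
        w = hist[:, d].max() - hist[:, d].min()
        if w > span:
            span = w
    if span < tol:
        return s, OK
    return s, NOT_CONVERGED


# ---------------------------------------------------------------------------
# Newton correction of a polynomial equilibrium at fixed parameter
# ---------------------------------------------------------------------------

@njit(cache=True)
def newton_poly(a, b, x0, y0, tol, maxit):
    x = x0
    y = y0
    for _ in range(maxit):
        fx, fy = poly_rhs(a, b, x, y)
        if np.sqrt(fx * fx + fy * fy) < tol:
            return x, y, True
        j11, j12, j21, j22 = poly_jac(a, b, x, y)
        det = j11 * j22 - j12 * j21
        if np.abs(det) < 1e-14:
            return x, y, False
        dx = (-fx * j22 + fy * j12) / det
        dy = (-fy * j11 + fx * j21) / det
        x += dx
        y += dy
        if not (np.isfinite(x) and np.isfinite(y)):
            return x, y, False
    fx, fy = poly_rhs(a, b, x, y)
    return x, y, np.sqrt(fx * fx + fy * fy) < tol


# ---------------------------------------------------------------------------
# pseudo-arclength continuation of a polynomial equilibrium branch
# ---------------------------------------------------------------------------

@njit(cache=True)
def continue_branch_poly(a0, b0, x_start, y_start, vidx, direction, ds0,
                         mu_span, max_pts, n_past, bound, root_tol, ds_min):
    """Continue the equilibrium branch varying coefficient ``vidx`` (0..19
    into the concatenated (a, b) vector) from a settled equilibrium.

    Returns (mu, x, y, re1, im1, re2, im2, n, status).  Stops ``n_past``
    points after the first sign change of lambda = re1, when |mu - mu0|
    exceeds ``mu_span``, after ``max_pts`` points, on divergence, or when
    the corrector still fails at the minimal arclength step (TRUNCATED).
    """
    a = a0.copy()
    b = b0.copy()
    eq_row = 0 if vidx < 10 else 1
    pidx = vidx if vidx < 10 else vidx - 10
    mu0 = a[vidx] if vidx < 10 else b[vidx - 10]

    mus = np.empty(max_pts)
    xs = np.empty(max_pts)
    ys = np.empty(max_pts)
    re1s = np.empty(max_pts)
    im1s = np.empty(max_pts)
    re2s = np.empty(max_pts)
    im2s = np.empty(max_pts)
    n = 0
    status = OK

    # polish the seed at mu0
    x, y, ok = newton_poly(a, b, x_start, y_start, root_tol, 50)
    if not ok:
        return mus, xs, ys, re1s, im1s, re2s, im2s, 0, TRUNCATED
    j11, j12, j21, j22 = poly_jac(a, b, x, y)
    r1, i1, r2, i2 = eig2(j11, j12, j21, j22)
    mus[0] = mu0; xs[0] = x; ys[0] = y
    re1s[0] = r1; im1s[0] = i1; re2s[0] = r2; im2s[0] = i2
    n = 1
    lam_prev = r1
    crossed = -1

    # initial tangent: J (tx, ty) = -f_mu, t_mu = 1, oriented by direction
    p = np.empty(10)
    _monomials(x, y, p)
    fm1 = p[pidx] if eq_row == 0 else 0.0
    fm2 = p[pidx] if eq_row == 1 else 0.0
    det = j11 * j22 - j12 * j21
    if np.abs(det) < 1e-12:
        return mus, xs, ys, re1s, im1s, re2s, im2s, n, TRUNCATED
    tx = (-fm1 * j22 + fm2 * j12) / det
    ty = (-fm2 * j11 + fm1 * j21) / det
    tmu = 1.0
    tn = np.sqrt(tx * tx + ty * ty + tmu * tmu)
    tx /= tn; ty /= tn; tmu /= tn
    if tmu * direction < 0.0:
        tx = -tx; ty = -ty; tmu = -tmu

    ds = ds0
    mu = mu0
    A = np.empty((3, 3))
    rhs = np.empty(3)
    while n < max_pts:
        # predictor
        xp = x + ds * tx
        yp = y + ds * ty
        mup = mu + ds * tmu
        # corrector: Newton on (f1, f2, t.(u - u_pred)) with t fixed
        xc = xp; yc = yp; muc = mup
        ok = False
        for _ in range(25):
            _set_coeff(a, b, vidx, muc)
            f1, f2 = poly_rhs(a, b, xc, yc)
            res3 = tx * (xc - xp) + ty * (yc - yp) + tmu * (muc - mup)
            if np.sqrt(f1 * f1 + f2 * f2) < root_tol and np.abs(res3) < root_tol:
                ok = True
                break
            j11, j12, j21, j22 = poly_jac(a, b, xc, yc)
            _monomials(xc, yc, p)
            fm1 = p[pidx] if eq_row == 0 else 0.0
            fm2 = p[pidx] if eq_row == 1 else 0.0
            A[0, 0] = j11; A[0, 1] = j12; A[0, 2] = fm1
            A[1, 0] = j21; A[1, 1] = j22; A[1, 2] = fm2
            A[2, 0] = tx; A[2, 1] = ty; A[2, 2] = tmu
            rhs[0] = -f1; rhs[1] = -f2; rhs[2] = -res3
            d = np.linalg.solve(A, rhs)
            xc += d[0]; yc += d[1]; muc += d[2]
            if not (np.isfinite(xc) and np.isfinite(yc) and np.isfinite(muc)):
                break
        if not ok:
            ds *= 0.5
            if ds < ds_min:
                status = TRUNCATED
                break
            continue
        # accept
        ntx = (xc - x) / ds
        nty = (yc - y) / ds
        ntmu = (muc - mu) / ds
        tn = np.sqrt(ntx * ntx + nty * nty + ntmu * ntmu)
        if tn > 1e-12:
            tx = ntx / tn; ty = nty / tn; tmu = ntmu / tn
        x = xc; y = yc; mu = muc
        if np.abs(x) > bound or np.abs(y) > bound:
            status = DIVERGED
            break
        j11, j12, j21, j22 = poly_jac(a, b, x, y)
        r1, i1, r2, i2 = eig2(j11, j12, j21, j22)
        mus[n] = mu; xs[n] = x; ys[n] = y
        re1s[n] = r1; im1s[n] = i1; re2s[n] = r2; im2s[n] = i2
        n += 1
        lam = r1
        if crossed < 0 and lam_prev < 0.0 and lam >= 0.0:
            crossed = n - 1
        lam_prev = lam
        if crossed >= 0 and n >= crossed + n_past:
            break
        if np.abs(mu - mu0) > mu_span:
            break
        ds = min(ds * 1.3, ds0 * 4.0)
    return mus[:n], xs[:n], ys[:n], re1s[:n], im1s[:n], re2s[:n], im2s[:n], n, status


# ---------------------------------------------------------------------------
# ramped integration drivers
# ---------------------------------------------------------------------------

@njit(cache=True)
def ramp_poly_lambda(a0, b0, vidx, x0, y0, mu0, rate_signed, mu_term, dt,
                     stride, bound, burn_steps):
    """Noise-free Euler ramp of a polynomial system, recording the recovery
    rate every ``stride`` steps.  Holds mu = mu0 for ``burn_steps`` first
    (discarded).  Returns (mus, lams, status); stops at the first recorded
    lambda >= 0, at mu_term, or on divergence.
    """
    a = a0.copy()
    b = b0.copy()
    n = int(np.ceil((mu_term - mu0) / (rate_signed * dt)))
    x = x0
    y = y0
    _set_coeff(a, b, vidx, mu0)
    for _ in range(burn_steps):
        fx, fy = poly_rhs(a, b, x, y)
        x += fx * dt
        y += fy * dt
    nrec = n // stride + 2
    mus = np.empty(nrec)
    lams = np.empty(nrec)
    k = 0
    mu = mu0
    status = OK
    for i in range(n):
        _set_coeff(a, b, vidx, mu)
        fx, fy = poly_rhs(a, b, x, y)
        x += fx * dt
        y += fy * dt
        mu = mu0 + rate_signed * dt * (i + 1)
        if np.abs(x) > bound or np.abs(y) > bound or not (np.isfinite(x) and np.isfinite(y)):
            status = DIVERGED
            break
        if i % stride == 0:
            _set_coeff(a, b, vidx, mu)
            lam = poly_lambda(a, b, x, y)
            mus[k] = mu
            lams[k] = lam
            k += 1
            if lam >= 0.0:
                break
    return mus[:k], lams[:k], status


@njit(cache=True)
def ramp_poly_noisy(a0, b0, vidx, x0, y0, mu0, rate_signed, mu_stop, dt,
                    noise, bound, burn_steps):
    """Euler-Maruyama ramp with pre-drawn per-step increments ``noise``
    (shape (2, burn_steps + n)).  The first ``burn_steps`` increments are
    consumed holding mu = mu0 (discarded from the output).  Returns
    (obs_x, n_done, status); obs_x[i] is the x coordinate after ramp step i,
    the parameter after step i is mu0 + rate_signed * dt * (i + 1).
    """
    a = a0.copy()
    b = b0.copy()
    x = x0
    y = y0
    _set_coeff(a, b, vidx, mu0)
    for j in range(burn_steps):
        fx, fy = poly_rhs(a, b, x, y)
        x += fx * dt + noise[0, j]
        y += fy * dt + noise[1, j]
    x0 = x
    y0 = y
    nmax = noise.shape[1] - burn_steps
    n = int(np.ceil((mu_stop - mu0) / (rate_signed * dt)))
    if n > nmax:
        n = nmax
    obs = np.empty(n)
    mu = mu0
    status = OK
    done = 0
    for i in range(n):
        _set_coeff(a, b, vidx, mu)
        fx, fy = poly_rhs(a, b, x, y)
        x += fx * dt + noise[0, burn_steps + i]
        y += fy * dt + noise[1, burn_steps + i]
        mu = mu0 + rate_signed * dt * (i + 1)
        obs[i] = x
        done = i + 1
        if np.abs(x) > bound or np.abs(y) > bound or not (np.isfinite(x) and np.isfinite(y)):
            status = DIVERGED
            break
    return obs[:done], done, status


@njit
def ramp_named_lambda(field, jac, s0, mu0, rate_signed, mu_term, dt, stride,
                      bound, n_past):
    """Noise-free Euler ramp of a named model; lambda from the analytic
    Jacobian via eigvals every ``stride`` steps.  Records ``n_past`` further
    points after the first nonnegative lambda (for interpolation context).
    """
    dim = s0.shape[0]
    s = s0.copy()
    out = np.empty(dim)
    J = np.empty((dim, dim))
    n = int(np.ceil((mu_term - mu0) / (rate_signed * dt)))
    nrec = n // stride + 2
    mus = np.empty(nrec)
    lams = np.empty(nrec)
    k = 0
    mu = mu0
    status = OK
    past = -1
    for i in range(n):
        field(s, mu, out)
        bad = False
        for d in range(dim):
            s[d] += out[d] * dt
            if np.abs(s[d]) > bound or not np.isfinite(s[d]):
                bad = True
        mu = mu0 + rate_signed * dt * (i + 1)
        if bad:
            status = DIVERGED
            break
        if i % stride == 0:
            jac(s, mu, J)
            ev = np.linalg.eigvals(J.astype(np.complex128))
            lam = -1e300
            for d in range(dim):
                if ev[d].real > lam:
                    lam = ev[d].real
            mus[k] = mu
            lams[k] = lam
            k += 1
            if lam >= 0.0 and past < 0:
                past = 0
            if past >= 0:
                past += 1
                if past > n_past:
                    break
    return mus[:k], lams[:k], status


@njit
def ramp_named_state(field, s0, mu0, rate_signed, mu_term, dt, bound):
    """Noise-free Euler ramp returning only the final state (used to track
    an attractor adiabatically from one parameter value to another)."""
    dim = s0.shape[0]
    s = s0.copy()
    out = np.empty(dim)
    n = int(np.ceil((mu_term - mu0) / (rate_signed * dt)))
    mu = mu0
    for i in range(n):
        field(s, mu, out)
        for d in range(dim):
            s[d] += out[d] * dt
            if np.abs(s[d]) > bound or not np.isfinite(s[d]):
                return s, DIVERGED
        mu = mu0 + rate_signed * dt * (i + 1)
    return s, OK


@njit
def ramp_named_noisy(field, s0, mu0, rate_signed, mu_stop, dt, noise,
                     obs_idx, bound, burn_steps):
    """Euler-Maruyama ramp of a named model with pre-drawn increments
    (shape (dim, burn_steps + n)); the first ``burn_steps`` hold mu = mu0
    and are discarded; records the observed coordinate per ramp step."""
    dim = s0.shape[0]
    s = s0.copy()
    out = np.empty(dim)
    for j in range(burn_steps):
        field(s, mu0, out)
        for d in range(dim):
            s[d] += out[d] * dt + noise[d, j]
    nmax = noise.shape[1] - burn_steps
    n = int(np.ceil((mu_stop - mu0) / (rate_signed * dt)))
    if n > nmax:
        n = nmax
    obs = np.empty(n)
    mu = mu0
    status = OK
    done = 0
    for i in range(n):
        field(s, mu, out)
        bad = False
        for d in range(dim):
            s[d] += out[d] * dt + noise[d, burn_steps + i]
            if np.abs(s[d]) > bound or not np.isfinite(s[d]):
                bad = True
        mu = mu0 + rate_signed * dt * (i + 1)
        obs[i] = s[obs_idx]
        done = i + 1
        if bad:
            status = DIVERGED
            break
    return obs[:done], done, status
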