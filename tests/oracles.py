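"""Independent oracles used by the tests.

Kept deliberately naive and separate from the package implementation:
closed-form two-body relaxation, a Newton solve of the discretized
steady-state equations, and bisection on the monotone rate response.
"""

import numpy as np
import scipy.optimize
import scipy.sparse


def two_body_final_gap(r_sum, d0, F, nu, dt, tol_disp=1e-3, n_iter=10_000):
    """Final center distance of two identical mobile disks relaxed from
    separation ``d0``: explicit Euler, both move, stopping once the
    per-disk step falls below ``tol_disp``."""
    d = d0
    for _ in range(n_iter):
        step = (dt / nu) * F * max(r_sum - d, 0.0)
        d = d + 2.0 * step
        if step < tol_disp:
            break
    return d


def neumann_laplacian(nx, ny):
    """Mirror-boundary 5-point Laplacian as a sparse matrix (row-major on
    (ix, iy) flattening), identical to the solver's stencil."""
    n = nx * ny
    rows, cols, vals = [], [], []

    def idx(i, j):
        return i * ny + j

    for i in range(nx):
        im = 1 if i == 0 else i - 1
        ip = nx - 2 if i == nx - 1 else i + 1
        for j in range(ny):
            jm = 1 if j == 0 else j - 1
            jp = ny - 2 if j == ny - 1 else j + 1
            k = idx(i, j)
            rows += [k] * 5
            cols += [idx(im, j), idx(ip, j), idx(i, jm), idx(i, jp), k]
            vals += [1.0, 1.0, 1.0, 1.0, -4.0]
    return scipy.sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))


def newton_steady_state(masks, delta_V, delta_T, params, x0=None,
                        dirichlet_vessels=False):
    """Solve the stationary discretized oxygen equations directly.

    With ``dirichlet_vessels`` the vessel-covered nodes are held at
    ``delta_V * gamma_max`` (the regime in which the vessel ceiling is
    active); otherwise the literal source-term equations are solved.
    """
    nx, ny = masks.vessel.shape
    L = neumann_laplacian(nx, ny) * (params.D_gamma / params.dx**2)
    influx = (delta_V * params.gamma_max * masks.vessel.astype(float)).ravel()
    upt = (params.uptake_scale
           * (delta_T * params.T_max * masks.tumor.astype(float)
              + params.stromal_node_weight * params.S_max
              * masks.stromal.astype(float))).ravel()
    vess = masks.vessel.ravel() > 0
    cap = delta_V * params.gamma_max

    if not dirichlet_vessels:
        def resid(g):
            return influx + L @ g - upt * g / (params.kappa_m + g)

        x0 = np.full(nx * ny, 1.0) if x0 is None else x0.ravel()
        sol = scipy.optimize.fsolve(resid, x0, full_output=False, xtol=1e-13)
        return sol.reshape(nx, ny)

    free = ~vess

    def resid(gf):
        g = np.empty(nx * ny)
        g[vess] = cap
        g[free] = gf
        r = (L @ g - upt * g / (params.kappa_m + g))
        return r[free]

    x0f = (np.full(free.sum(), cap * 0.5) if x0 is None else x0.ravel()[free])
    sol = scipy.optimize.fsolve(resid, x0f, full_output=False, xtol=1e-13)
    g = np.empty(nx * ny)
    g[vess] = cap
    g[free] = sol
    return g.reshape(nx, ny)


def bisect_rate(simulate_endpoint, target, lo, hi, tol=1e-6, increasing=True):
    """Bisection on a monotone endpoint response; cross-check for the
    pattern search. Returns the rate whose endpoint is closest to target."""
    f_lo, f_hi = simulate_endpoint(lo), simulate_endpoint(hi)
    if not increasing:
        lo, hi, f_lo, f_hi = hi, lo, f_hi, f_lo
    if target <= min(f_lo, f_hi):
        return lo if f_lo < f_hi else hi
    if target >= max(f_lo, f_hi):
        return hi if f_hi > f_lo else lo
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if abs(hi - lo) < tol:
            return mid
        if simulate_endpoint(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
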