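"""Numba kernels for force relaxation and explicit oxygen stepping.

These are performance backends only; the public API and the reference
(numpy) implementations live in :mod:`oxyvoxel.tissue` and
:mod:`oxyvoxel.oxygen`. The binned neighbor search must produce the same
forces as the all-pairs reference to float64 precision, and the stepping
kernel the same update as the numpy reference step (up to floating-point
reassociation permitted for vectorization).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# neighbor binning helpers
# ---------------------------------------------------------------------------


@njit(cache=False)
def _bin_points(x, y, xmin, ymin, nbx, nby, s):
    """Counting-sort points into a uniform grid of bin size ``s``.

    Returns (start, order): ``order[start[b]:start[b+1]]`` lists the point
    indices in bin ``b = bx * nby + by``.
    """
    n = x.shape[0]
    nb = nbx * nby
    binof = np.empty(n, np.int64)
    counts = np.zeros(nb + 1, np.int64)
    for i in range(n):
        bx = int((x[i] - xmin) / s)
        by = int((y[i] - ymin) / s)
        if bx < 0:
            bx = 0
        elif bx >= nbx:
            bx = nbx - 1
        if by < 0:
            by = 0
        elif by >= nby:
            by = nby - 1
        b = bx * nby + by
        binof[i] = b
        counts[b + 1] += 1
    for b in range(nb):
        counts[b + 1] += counts[b]
    order = np.empty(n, np.int64)
    fill = counts.copy()
    for i in range(n):
        b = binof[i]
        order[fill[b]] = i
        fill[b] += 1
    return counts, order


@njit(cache=False)
def _cell_forces(px, py, rad, vx, vy, rv, F, xmin, ymin, nbx, nby, sc,
                 vstart, vorder, nvbx, nvby, sv, jit_cos, jit_sin, fx, fy):
    """Total repulsive force on every mobile cell (cells + static vessels).

    Exactly equivalent to the all-pairs Hookean sum; bin sizes must be at
    least the largest interaction distance of their pair class.
    """
    n = px.shape[0]
    start, order = _bin_points(px, py, xmin, ymin, nbx, nby, sc)
    for i in range(n):
        fxi = 0.0
        fyi = 0.0
        bx = int((px[i] - xmin) / sc)
        by = int((py[i] - ymin) / sc)
        if bx < 0:
            bx = 0
        elif bx >= nbx:
            bx = nbx - 1
        if by < 0:
            by = 0
        elif by >= nby:
            by = nby - 1
        for dbx in range(-1, 2):
            cbx = bx + dbx
            if cbx < 0 or cbx >= nbx:
                continue
            for dby in range(-1, 2):
                cby = by + dby
                if cby < 0 or cby >= nby:
                    continue
                b = cbx * nby + cby
                for k in range(start[b], start[b + 1]):
                    j = order[k]
                    if j == i:
                        continue
                    rsum = rad[i] + rad[j]
                    ddx = px[i] - px[j]
                    ddy = py[i] - py[j]
                    d2 = ddx * ddx + ddy * ddy
                    if d2 >= rsum * rsum:
                        continue
                    d = np.sqrt(d2)
                    if d < 1e-9:
                        # coincident centers: seeded per-cell direction
                        fxi += F * rsum * jit_cos[i]
                        fyi += F * rsum * jit_sin[i]
                    else:
                        mag = F * (rsum - d) / d
                        fxi += mag * ddx
                        fyi += mag * ddy
        # static vessels
        vbx = int((px[i] - xmin) / sv)
        vby = int((py[i] - ymin) / sv)
        if vbx < 0:
            vbx = 0
        elif vbx >= nvbx:
            vbx = nvbx - 1
        if vby < 0:
            vby = 0
        elif vby >= nvby:
            vby = nvby - 1
        for dbx in range(-1, 2):
            cbx = vbx + dbx
            if cbx < 0 or cbx >= nvbx:
                continue
            for dby in range(-1, 2):
                cby = vby + dby
                if cby < 0 or cby >= nvby:
                    continue
                b = cbx * nvby + cby
                for k in range(vstart[b], vstart[b + 1]):
                    j = vorder[k]
                    rsum = rad[i] + rv
                    ddx = px[i] - vx[j]
                    ddy = py[i] - vy[j]
                    d2 = ddx * ddx + ddy * ddy
                    if d2 >= rsum * rsum:
                        continue
                    d = np.sqrt(d2)
                    if d < 1e-9:
                        fxi += F * rsum * jit_cos[i]
                        fyi += F * rsum * jit_sin[i]
                    else:
                        mag = F * (rsum - d) / d
                        fxi += mag * ddx
                        fyi += mag * ddy
        fx[i] = fxi
        fy[i] = fyi


@njit(cache=False)
def relax_loop(px, py, rad, vx, vy, rv, F, nu, dt, xmin, xmax, ymin, ymax,
               tol_disp, max_iter, stall_window, stall_rtol,
               jit_cos, jit_sin):
    """Overdamped explicit-Euler relaxation of mobile cells.

    Returns (iterations, final max displacement, status) with status
    1 = converged (max step displacement < tol_disp), 0 = iteration cap,
    2 = stalled (displacement plateau: jammed packing).
    """
    n = px.shape[0]
    if n == 0:
        return 0, 0.0, 1
    rmax = 0.0
    for i in range(n):
        if rad[i] > rmax:
            rmax = rad[i]
    sc = 2.0 * rmax
    sv = rv + rmax
    nbx = max(1, int((xmax - xmin) / sc) + 1)
    nby = max(1, int((ymax - ymin) / sc) + 1)
    nvbx = max(1, int((xmax - xmin) / sv) + 1)
    nvby = max(1, int((ymax - ymin) / sv) + 1)
    vstart, vorder = _bin_points(vx, vy, xmin, ymin, nvbx, nvby, sv)
    fx = np.empty(n)
    fy = np.empty(n)
    mob = dt / nu
    maxd = 0.0
    win_best = 1e300
    prev_best = 1e300
    it = 0
    for it in range(1, max_iter + 1):
        _cell_forces(px, py, rad, vx, vy, rv, F, xmin, ymin, nbx, nby, sc,
                     vstart, vorder, nvbx, nvby, sv, jit_cos, jit_sin, fx, fy)
        maxd = 0.0
        for i in range(n):
            ddx = mob * fx[i]
            ddy = mob * fy[i]
            nxp = px[i] + ddx
            nyp = py[i] + ddy
            if nxp < xmin:
                nxp = xmin
            elif nxp > xmax:
                nxp = xmax
            if nyp < ymin:
                nyp = ymin
            elif nyp > ymax:
                nyp = ymax
            ddx = nxp - px[i]
            ddy = nyp - py[i]
            d = np.sqrt(ddx * ddx + ddy * ddy)
            if d > maxd:
                maxd = d
            px[i] = nxp
            py[i] = nyp
        if maxd < tol_disp:
            return it, maxd, 1
        if maxd < win_best:
            win_best = maxd
        if it % stall_window == 0:
            if win_best > stall_rtol * prev_best:
                return it, maxd, 2
            prev_best = win_best
            win_best = 1e300
    return it, maxd, 0


@njit(cache=False)
def count_overlaps(px, py, rad, vx, vy, rv, tol):
    """Number of overlapping cell-cell and cell-vessel pairs and the
    overlap-squared energy proxy (vessel-vessel overlap is permitted)."""
    n = px.shape[0]
    nv = vx.shape[0]
    cnt = 0
    energy = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            rsum = rad[i] + rad[j]
            ddx = px[i] - px[j]
            ddy = py[i] - py[j]
            d2 = ddx * ddx + ddy * ddy
            if d2 < (rsum - tol) * (rsum - tol):
                cnt += 1
                ov = rsum - np.sqrt(d2)
                energy += ov * ov
        for j in range(nv):
            rsum = rad[i] + rv
            ddx = px[i] - vx[j]
            ddy = py[i] - vy[j]
            d2 = ddx * ddx + ddy * ddy
            if d2 < (rsum - tol) * (rsum - tol):
                cnt += 1
                ov = rsum - np.sqrt(d2)
                energy += ov * ov
    return cnt, energy


@njit(cache=False)
def count_overlaps_binned(px, py, rad, vx, vy, rv, tol, xmin, xmax, ymin, ymax):
    """Binned version of :func:`count_overlaps` for large layouts."""
    n = px.shape[0]
    rmax = 0.0
    for i in range(n):
        if rad[i] > rmax:
            rmax = rad[i]
    if n == 0:
        return 0, 0.0
    sc = 2.0 * rmax
    sv = rv + rmax
    nbx = max(1, int((xmax - xmin) / sc) + 1)
    nby = max(1, int((ymax - ymin) / sc) + 1)
    start, order = _bin_points(px, py, xmin, ymin, nbx, nby, sc)
    nvbx = max(1, int((xmax - xmin) / sv) + 1)
    nvby = max(1, int((ymax - ymin) / sv) + 1)
    vstart, vorder = _bin_points(vx, vy, xmin, ymin, nvbx, nvby, sv)
    cnt = 0
    energy = 0.0
    for i in range(n):
        bx = min(max(int((px[i] - xmin) / sc), 0), nbx - 1)
        by = min(max(int((py[i] - ymin) / sc), 0), nby - 1)
        for dbx in range(-1, 2):
            cbx = bx + dbx
            if cbx < 0 or cbx >= nbx:
                continue
            for dby in range(-1, 2):
                cby = by + dby
                if cby < 0 or cby >= nby:
                    continue
                b = cbx * nby + cby
                for k in range(start[b], start[b + 1]):
                    j = order[k]
                    if j <= i:
                        continue
                    rsum = rad[i] + rad[j]
                    ddx = px[i] - px[j]
                    ddy = py[i] - py[j]
                    d2 = ddx * ddx + ddy * ddy
                    if d2 < (rsum - tol) * (rsum - tol):
                        cnt += 1
                        ov = rsum - np.sqrt(d2)
                        energy += ov * ov
        vbx = min(max(int((px[i] - xmin) / sv), 0), nvbx - 1)
        vby = min(max(int((py[i] - ymin) / sv), 0), nvby - 1)
        for dbx in range(-1, 2):
            cbx = vbx + dbx
            if cbx < 0 or cbx >= nvbx:
                continue
            for dby in range(-1, 2):
                cby = vby + dby
                if cby < 0 or cby >= nvby:
                    continue
                b = cbx * nvby + cby
                for k in range(vstart[b], vstart[b + 1]):
                    j = vorder[k]
                    rsum = rad[i] + rv
                    ddx = px[i] - vx[j]
                    ddy = py[i] - vy[j]
                    d2 = ddx * ddx + ddy * ddy
                    if d2 < (rsum - tol) * (rsum - tol):
                        cnt += 1
                        ov = rsum - np.sqrt(d2)
                        energy += ov * ov
    return cnt, energy


# ---------------------------------------------------------------------------
# oxygen reaction-diffusion stepping
# ---------------------------------------------------------------------------


@njit(cache=False)
def add_disk_counts(counts, cx, cy, R, xmin, ymin, dx):
    """Increment ``counts[ix, iy]`` for every grid node strictly inside a
    disk of radius ``R`` around each center (strict Euclidean inequality)."""
    nx, ny = counts.shape
    r2 = R * R
    for e in range(cx.shape[0]):
        i0 = int(np.ceil((cx[e] - R - xmin) / dx))
        i1 = int(np.floor((cx[e] + R - xmin) / dx))
        j0 = int(np.ceil((cy[e] - R - ymin) / dx))
        j1 = int(np.floor((cy[e] + R - ymin) / dx))
        if i0 < 0:
            i0 = 0
        if j0 < 0:
            j0 = 0
        if i1 > nx - 1:
            i1 = nx - 1
        if j1 > ny - 1:
            j1 = ny - 1
        for i in range(i0, i1 + 1):
            ddx = xmin + i * dx - cx[e]
            for j in range(j0, j1 + 1):
                ddy = ymin + j * dx - cy[e]
                if ddx * ddx + ddy * ddy < r2:
                    counts[i, j] += 1


@njit(cache=False, fastmath={"reassoc", "contract"})
def advance_oxygen(g, src, upt, werr, vi, vj, cap, use_cap, alpha, kappa,
                   max_steps, eps_thr, sqrt_norm):
    """Run forward-Euler steps of the oxygen equation until the normalized
    per-step error drops below ``eps_thr`` or ``max_steps`` is reached.

    Parameters are pre-multiplied: ``src`` is the per-node influx increment
    per step (delta_V * gamma_max * vessel_count * dt), ``upt`` the per-node
    uptake prefactor per step ((delta_T*Tmax + Smax-weighted) * scale * dt)
    applied to ``g/(kappa+g)``. ``(vi, vj)`` list the vessel-covered nodes,
    capped at the intravascular level ``cap = delta_V * gamma_max`` when
    ``use_cap``; 5-point Laplacian with mirror (no-flux) boundaries; the
    field is clipped at zero.

    ``werr`` weights the per-node error accumulation: zero on vessel nodes
    while the cap is active — their (post-cap) contribution is added in
    the cap pass instead, because adding the large pre-cap term in the
    main loop and subtracting it afterwards cancels catastrophically and
    corrupts the convergence error.

    Returns (steps, eps_bar, status): 1 converged, 0 step cap, -1 diverged.
    Modifies ``g`` in place.
    """
    nx, ny = g.shape
    nn = nx * ny
    a = g
    b = np.empty_like(g)
    in_g = True
    eps = np.inf
    steps = 0
    for step in range(max_steps):
        err2 = 0.0
        for i in range(nx):
            im = i - 1 if i > 0 else 1
            ip = i + 1 if i < nx - 1 else nx - 2
            # mirrored y boundaries
            c = a[i, 0]
            val = c + alpha * (a[im, 0] + a[ip, 0] + 2.0 * a[i, 1] - 4.0 * c) \
                + src[i, 0] - upt[i, 0] * c / (kappa + c)
            val = max(val, 0.0)
            b[i, 0] = val
            d = val - c
            err2 += werr[i, 0] * d * d
            c = a[i, ny - 1]
            val = c + alpha * (a[im, ny - 1] + a[ip, ny - 1]
                               + 2.0 * a[i, ny - 2] - 4.0 * c) \
                + src[i, ny - 1] - upt[i, ny - 1] * c / (kappa + c)
            val = max(val, 0.0)
            b[i, ny - 1] = val
            d = val - c
            err2 += werr[i, ny - 1] * d * d
            for j in range(1, ny - 1):
                c = a[i, j]
                lap = a[im, j] + a[ip, j] + a[i, j - 1] + a[i, j + 1] - 4.0 * c
                val = c + alpha * lap + src[i, j] - upt[i, j] * c / (kappa + c)
                val = max(val, 0.0)
                b[i, j] = val
                d = val - c
                err2 += werr[i, j] * d * d
        if use_cap:
            for t in range(vi.shape[0]):
                ii = vi[t]
                jj = vj[t]
                val = b[ii, jj]
                if val > cap:
                    val = cap
                    b[ii, jj] = val
                d = val - a[ii, jj]
                err2 += d * d
        steps = step + 1
        tmp = a
        a = b
        b = tmp
        in_g = not in_g
        if not np.isfinite(err2):
            if not in_g:
                g[:, :] = a
            return steps, np.inf, -1
        eps = (np.sqrt(err2) / nn) if sqrt_norm else (err2 / nn)
        if eps <= eps_thr:
            break
    if not in_g:
        g[:, :] = a
    status = 1 if eps <= eps_thr else 0
    return steps, eps, status
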