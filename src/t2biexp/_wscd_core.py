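"""Compiled inner loop of the weighted stochastic conjugate-direction fitter.

Everything here is specialised to the five-parameter weighted biexponential
objective so the whole per-voxel search (grid probing, Brent refinement,
direction cycling, the stochastic candidate list) runs without Python
overhead.  The generic, callable-agnostic versions of the line search and
the direction cycle live in :mod:`t2biexp.wscd`.

The kernel works in a normalised parameter space — relaxation times in ms,
amplitudes and offset in units of one hundredth of the voxel's maximum
intensity — so that the uniform initial step length is meaningful on every
axis; the caller supplies the per-axis ``scale`` vector.

Randomness is a splitmix64 counter seeded per voxel, so a fit is a pure
function of (series, weights, config, seed).
"""

import numpy as np
from numba import njit

_GOLD = 0.3819660112501051  # 2 - golden ratio
_ZEPS = 1e-12
_SEC_PER_LINE = 4  # secondary line-search minima kept per direction
_SEC_PER_CYCLE = 16
_MAX_DOUBLINGS = 40  # segment extensions before a line search gives up


@njit(cache=True)
def _rand_next(state):
    """splitmix64 step; ``state`` is a 1-element uint64 array."""
    state[0] = state[0] + np.uint64(0x9E3779B97F4A7C15)
    z = state[0]
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


@njit(cache=True)
def _rand_below(state, n):
    return np.int64(_rand_next(state) % np.uint64(n))


@njit(cache=True)
def _objective(x, scale, te, y, w):
    """Weighted residual sum of squares at the scaled parameter vector
    x = (T_S, T_L, A_S/sA, A_L/sA, n/sA)."""
    t_s = x[0] * scale[0]
    t_l = x[1] * scale[1]
    a_s = x[2] * scale[2]
    a_l = x[3] * scale[3]
    n = x[4] * scale[4]
    acc = 0.0
    for i in range(te.size):
        m = w[i] * a_s * np.exp(-te[i] / t_s) + w[i] * a_l * np.exp(-te[i] / t_l) \
            + n - y[i]
        acc += m * m
    if not np.isfinite(acc):
        return np.inf
    return acc


@njit(cache=True)
def _line_obj(base, d, s, scale, te, y, w, lo, hi, scratch):
    """Objective along the segment, with the probe projected into the box."""
    for j in range(5):
        v = base[j] + s * d[j]
        if v < lo[j]:
            v = lo[j]
        elif v > hi[j]:
            v = hi[j]
        scratch[j] = v
    return _objective(scratch, scale, te, y, w)


@njit(cache=True)
def _brent(base, d, a, b, x0, f0, scale, te, y, w, lo, hi, scratch, tol, maxit):
    """Brent minimisation of the line objective on [a, b] starting from x0."""
    x = x0
    wv = x0
    v = x0
    fx = f0
    fw = f0
    fv = f0
    e = 0.0
    step = 0.0
    for _ in range(maxit):
        xm = 0.5 * (a + b)
        tol1 = tol * abs(x) + _ZEPS
        tol2 = 2.0 * tol1
        if abs(x - xm) <= tol2 - 0.5 * (b - a):
            break
        use_golden = True
        if abs(e) > tol1:
            r = (x - wv) * (fx - fv)
            q = (x - v) * (fx - fw)
            p = (x - v) * q - (x - wv) * r
            q = 2.0 * (q - r)
            if q > 0.0:
                p = -p
            q = abs(q)
            etemp = e
            e = step
            if abs(p) < abs(0.5 * q * etemp) and p > q * (a - x) and p < q * (b - x):
                step = p / q
                u = x + step
                if u - a < tol2 or b - u < tol2:
                    step = tol1 if xm - x >= 0.0 else -tol1
                use_golden = False
        if use_golden:
            e = (a - x) if x >= xm else (b - x)
            step = _GOLD * e
        if abs(step) >= tol1:
            u = x + step
        else:
            u = x + (tol1 if step >= 0.0 else -tol1)
        fu = _line_obj(base, d, u, scale, te, y, w, lo, hi, scratch)
        if fu <= fx:
            if u >= x:
                a = x
            else:
                b = x
            v = wv
            fv = fw
            wv = x
            fw = fx
            x = u
            fx = fu
        else:
            if u < x:
                a = u
            else:
                b = u
            if fu <= fw or wv == x:
                v = wv
                fv = fw
                wv = u
                fw = fu
            elif fu <= fv or v == x or v == wv:
                v = u
                fv = fu
    return x, fx


@njit(cache=True)
def _segment_search(point, vwork, m, scale, te, y, w, lo, hi, brent_tol,
                    brent_maxit, scratch, grid_g, cidx, base, dvec,
                    sec_s, sec_f, keep_below):
    """Line minimisation along the bidirectional segment [point-v, point+v].

    The objective is probed at m+1 grid points; while the best probe sits
    at a segment end the segment is doubled (bracket expansion), so the
    line is minimised over its whole improving range.  Within the final
    segment, the probe maxima split it into unimodal pieces and the
    interior minimum of every piece is Brent-refined; both endpoints stay
    candidates.  ``vwork`` holds the (possibly extended) direction on exit.

    Returns (best_s, best_f, n_sec) with best_s in [0, 1] relative to the
    final segment; alternative refined minima with f < keep_below are
    written to the secondary buffers.
    """
    for _ in range(_MAX_DOUBLINGS):
        for j in range(5):
            base[j] = point[j] - vwork[j]
            dvec[j] = 2.0 * vwork[j]
        for k in range(m + 1):
            grid_g[k] = _line_obj(base, dvec, k / m, scale, te, y, w, lo, hi,
                                  scratch)
        kbest = 0
        for k in range(1, m + 1):
            if grid_g[k] < grid_g[kbest]:
                kbest = k
        if kbest != 0 and kbest != m:
            break
        grew = False
        for j in range(5):
            nv = 2.0 * vwork[j]
            if np.isfinite(nv):
                vwork[j] = nv
                grew = True
        if not grew:
            break
    # C set: endpoints plus grid-local maxima
    nc = 0
    cidx[nc] = 0
    nc += 1
    for k in range(1, m):
        if grid_g[k] > grid_g[k - 1] and grid_g[k] > grid_g[k + 1]:
            cidx[nc] = k
            nc += 1
    cidx[nc] = m
    nc += 1
    if grid_g[0] <= grid_g[m]:
        best_s = 0.0
        best_f = grid_g[0]
    else:
        best_s = 1.0
        best_f = grid_g[m]
    n_sec = 0
    for j in range(nc - 1):
        c0 = cidx[j]
        c1 = cidx[j + 1]
        if c1 - c0 < 2:
            continue
        kmin = c0 + 1
        for k in range(c0 + 2, c1):
            if grid_g[k] < grid_g[kmin]:
                kmin = k
        if not np.isfinite(grid_g[kmin]):
            continue
        if not (grid_g[kmin] < grid_g[c0] and grid_g[kmin] < grid_g[c1]):
            continue  # no strict bracket (flat stretch)
        a = (kmin - 1) / m
        b = (kmin + 1) / m
        s_ref, f_ref = _brent(base, dvec, a, b, kmin / m, grid_g[kmin],
                              scale, te, y, w, lo, hi, scratch,
                              brent_tol, brent_maxit)
        if f_ref < best_f:
            if best_f < keep_below and best_s != 0.0 and best_s != 1.0 \
                    and n_sec < sec_s.size:
                sec_s[n_sec] = best_s
                sec_f[n_sec] = best_f
                n_sec += 1
            best_s = s_ref
            best_f = f_ref
        elif f_ref < keep_below and n_sec < sec_s.size:
            sec_s[n_sec] = s_ref
            sec_f[n_sec] = f_ref
            n_sec += 1
    return best_s, best_f, n_sec


@njit(cache=True)
def _apply_move(point, base, dvec, s, lo, hi):
    for j in range(5):
        v = base[j] + s * dvec[j]
        if v < lo[j]:
            v = lo[j]
        elif v > hi[j]:
            v = hi[j]
        point[j] = v


@njit(cache=True)
def _powell_cycle(point, dirs, f_start, scale, te, y, w, lo, hi, m, tol,
                  brent_tol, brent_maxit, scratch, grid_g, cidx,
                  line_sec_s, line_sec_f, sec_pts, sec_f, base, dvec, vwork):
    """One conjugate-direction cycle: bidirectional (segment-extending)
    line minimisation along each of the 5 directions, then the classic
    replacement test — the direction of largest single decrease is replaced
    by the net displacement when the extrapolation criterion accepts it.
    ``point`` and ``dirs`` are updated in place; alternative line minima
    are emitted through ``sec_pts``/``sec_f``.
    """
    start = np.empty(5)
    for j in range(5):
        start[j] = point[j]
    f0 = f_start
    f_cur = f_start
    delta = 0.0
    ibig = 0
    n_sec = 0
    for i in range(5):
        nv = 0.0
        for j in range(5):
            vwork[j] = dirs[i, j]
            nv += vwork[j] * vwork[j]
        if nv < _ZEPS * _ZEPS:
            continue
        best_s, best_f, nls = _segment_search(
            point, vwork, m, scale, te, y, w, lo, hi, brent_tol, brent_maxit,
            scratch, grid_g, cidx, base, dvec, line_sec_s, line_sec_f,
            f_cur - tol)
        for q in range(nls):
            if n_sec < sec_pts.shape[0]:
                _apply_move(sec_pts[n_sec], base, dvec, line_sec_s[q], lo, hi)
                sec_f[n_sec] = line_sec_f[q]
                n_sec += 1
        if best_f < f_cur:
            if f_cur - best_f > delta:
                delta = f_cur - best_f
                ibig = i
            _apply_move(point, base, dvec, best_s, lo, hi)
            f_cur = best_f
    # extrapolation test (classic conjugate-direction bookkeeping): replace
    # the largest-decrease direction with the displacement only when doing
    # so is predicted to help
    dnorm = 0.0
    for j in range(5):
        dj = point[j] - start[j]
        dnorm += dj * dj
    if dnorm > _ZEPS * _ZEPS:
        for j in range(5):
            scratch[j] = start[j] + 2.0 * (point[j] - start[j])
            if scratch[j] < lo[j]:
                scratch[j] = lo[j]
            elif scratch[j] > hi[j]:
                scratch[j] = hi[j]
        f_e = _objective(scratch, scale, te, y, w)
        if f_e < f0:
            t = 2.0 * (f0 - 2.0 * f_cur + f_e) * (f0 - f_cur - delta) ** 2 \
                - delta * (f0 - f_e) ** 2
            if t < 0.0:
                for j in range(5):
                    vwork[j] = point[j] - start[j]
                best_s, best_f, nls = _segment_search(
                    point, vwork, m, scale, te, y, w, lo, hi,
                    brent_tol, brent_maxit, scratch, grid_g, cidx, base,
                    dvec, line_sec_s, line_sec_f, f_cur - tol)
                if best_f < f_cur:
                    _apply_move(point, base, dvec, best_s, lo, hi)
                    f_cur = best_f
                for j in range(5):
                    dirs[ibig, j] = point[j] - start[j]
    return f_cur, n_sec


@njit(cache=True)
def _push(pts, dsets, objs, active, cap, p, dset, f):
    """Insert a state, evicting the worst member when the list is full."""
    if active < cap:
        for j in range(5):
            pts[active, j] = p[j]
            for k in range(5):
                dsets[active, j, k] = dset[j, k]
        objs[active] = f
        return active + 1
    iw = 0
    for i in range(1, active):
        if objs[i] > objs[iw]:
            iw = i
    if f < objs[iw]:
        for j in range(5):
            pts[iw, j] = p[j]
            for k in range(5):
                dsets[iw, j, k] = dset[j, k]
        objs[iw] = f
    return active


@njit(cache=True)
def wscd_kernel(te, y, w, b0, scale, step, seed, max_iter, m, tol, cap,
                brent_tol, brent_maxit, lo, hi, trace):
    """Full stochastic conjugate-direction minimisation for one voxel.

    All points and bounds are in the normalised parameter space; ``scale``
    converts to physical units inside the objective.  Returns
    (best_point, best_objective, iterations, converged); ``trace`` (length
    >= max_iter) receives the best objective after each iteration.
    """
    pts = np.empty((cap, 5))
    dsets = np.empty((cap, 5, 5))
    objs = np.empty(cap)
    scratch = np.empty(5)
    grid_g = np.empty(m + 1)
    cidx = np.empty(m + 2, np.int64)
    line_sec_s = np.empty(_SEC_PER_LINE)
    line_sec_f = np.empty(_SEC_PER_LINE)
    sec_pts = np.empty((_SEC_PER_CYCLE, 5))
    sec_f = np.empty(_SEC_PER_CYCLE)
    base = np.empty(5)
    dvec = np.empty(5)
    vwork = np.empty(5)
    rng = np.empty(1, np.uint64)
    rng[0] = seed

    # initial state: clipped start point, axis-aligned directions of length `step`
    p0 = np.empty(5)
    for j in range(5):
        v = b0[j]
        if v < lo[j]:
            v = lo[j]
        elif v > hi[j]:
            v = hi[j]
        p0[j] = v
    d0 = np.zeros((5, 5))
    for j in range(5):
        d0[j, j] = step
    f0 = _objective(p0, scale, te, y, w)
    active = _push(pts, dsets, objs, 0, cap, p0, d0, f0)
    best_p = p0.copy()
    best_f = f0
    prev_best = np.empty(5)

    sel_pts = np.empty((10, 5))
    sel_dsets = np.empty((10, 5, 5))
    sel_objs = np.empty(10)
    idx = np.empty(cap, np.int64)
    keep = np.empty(cap, np.bool_)

    n_iter = 0
    converged = False
    for it in range(max_iter):
        if active == 0:
            converged = True
            break
        n_iter = it + 1
        for j in range(5):
            prev_best[j] = best_p[j]
        # select the current best plus up to 9 uniformly random other states
        for i in range(active):
            idx[i] = i
        ib = 0
        for i in range(1, active):
            if objs[i] < objs[ib]:
                ib = i
        idx[0], idx[ib] = idx[ib], idx[0]
        nsel = active if active < 10 else 10
        for j in range(1, nsel):
            r = j + _rand_below(rng, active - j)
            idx[j], idx[r] = idx[r], idx[j]
        for j in range(nsel):
            i = idx[j]
            for a in range(5):
                sel_pts[j, a] = pts[i, a]
                for b in range(5):
                    sel_dsets[j, a, b] = dsets[i, a, b]
            sel_objs[j] = objs[i]
        # pull selected states out of the list
        for i in range(active):
            keep[i] = True
        for j in range(nsel):
            keep[idx[j]] = False
        na = 0
        for i in range(active):
            if keep[i]:
                if na != i:
                    for a in range(5):
                        pts[na, a] = pts[i, a]
                        for b in range(5):
                            dsets[na, a, b] = dsets[i, a, b]
                    objs[na] = objs[i]
                na += 1
        active = na
        # run one conjugate-direction cycle on each selected state
        for j in range(nsel):
            f_new, nsec = _powell_cycle(
                sel_pts[j], sel_dsets[j], sel_objs[j], scale, te, y, w, lo,
                hi, m, tol, brent_tol, brent_maxit, scratch, grid_g, cidx,
                line_sec_s, line_sec_f, sec_pts, sec_f, base, dvec, vwork)
            if f_new < sel_objs[j]:
                active = _push(pts, dsets, objs, active, cap,
                               sel_pts[j], sel_dsets[j], f_new)
            if f_new < best_f:
                best_f = f_new
                for a in range(5):
                    best_p[a] = sel_pts[j, a]
            for q in range(nsec):
                active = _push(pts, dsets, objs, active, cap,
                               sec_pts[q], sel_dsets[j], sec_f[q])
                if sec_f[q] < best_f:
                    best_f = sec_f[q]
                    for a in range(5):
                        best_p[a] = sec_pts[q, a]
        trace[it] = best_f
        delta = 0.0
        for a in range(5):
            da = abs(best_p[a] - prev_best[a])
            if da > delta:
                delta = da
        if delta < tol:
            converged = True
            break
    return best_p, best_f, n_iter, converged
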