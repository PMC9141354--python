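"""Weighted stochastic conjugate-direction (WSCD) fitting.

The fitter minimises the weighted biexponential objective without
derivatives.  From a log-linear monoexponential starting point it runs
conjugate-direction cycles: along each search direction the objective is
probed on a uniform grid over a bidirectional segment, every bracketed local
minimum is refined with Brent's method, and the net displacement of a cycle
replaces the direction that contributed most to it (Powell's recipe).  All
local minima met on the way are kept on a candidate list; each iteration
re-expands the current best state plus a random sample of stored states, so
the search can escape local basins of the (multi-modal) biexponential
landscape.  The whole procedure is deterministic given a seed.

:func:`segmented_line_search` and :func:`powell_cycle` are generic reference
implementations that accept any objective callable; :func:`wscd_fit` runs
the compiled kernel specialised to the weighted biexponential objective.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import optimize

from . import _wscd_core
from .signal_model import (
    AMP_FLOOR_FRACTION,
    CLAMP_T_MAX,
    CLAMP_T_MIN,
    BiexpParams,
    EchoSeries,
    FitResult,
    OutcomeClass,
    classify_fit,
    param_bounds,
)

__all__ = [
    "WSCDConfig",
    "LineMinimum",
    "loglinear_init",
    "segmented_line_search",
    "powell_cycle",
    "wscd_fit",
]


@dataclass(frozen=True)
class WSCDConfig:
    """Optimiser settings.

    Attributes
    ----------
    max_iterations
        Cap on stochastic-list iterations.
    subsegments
        Number of equal subsegments the line-search segment is divided
        into (the grid has ``subsegments + 1`` probes).
    initial_step
        Length of the initial axis-aligned search vectors.
    tol
        Both the "significant improvement" threshold for keeping a state
        and the stopping threshold on the best point's componentwise change.
    list_capacity
        Maximum number of stored candidate states (worst evicted first).
    brent_tol, brent_max_iterations
        Relative tolerance and iteration cap of the Brent refinement.
    seed
        Default RNG seed for the stochastic state selection.
    """

    max_iterations: int = 200
    subsegments: int = 20
    initial_step: float = 10.0
    tol: float = 1e-4
    list_capacity: int = 64
    brent_tol: float = 1e-6
    brent_max_iterations: int = 100
    seed: int = 0


def loglinear_init(series: EchoSeries) -> BiexpParams:
    """Starting point from a log-linear monoexponential fit.

    Ordinary least squares of ``ln y`` on ``t`` over the echoes with
    positive intensity gives a monoexponential (T, A); the biexponential
    start splits it as T_S = 0.75 T, T_L = 1.25 T, A_S = A_L = A/2, n = 0.
    When fewer than two positive echoes exist (or the decay rate comes out
    non-positive), T falls back to the mid-range of the echo times and A to
    the maximum intensity.
    """
    t = series.echo_times
    y = series.intensities
    pos = y > 0
    t2 = a = None
    if np.count_nonzero(pos) >= 2:
        slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
        if slope < 0:
            t2 = -1.0 / slope
            a = float(np.exp(intercept))
    if t2 is None:
        t2 = 0.5 * (t[0] + t[-1])
        a = float(np.max(y)) if np.max(y) > 0 else 1.0
    t2 = float(np.clip(t2, CLAMP_T_MIN / 0.75, CLAMP_T_MAX / 1.25))
    return BiexpParams(a_s=a / 2, a_l=a / 2, t_s=0.75 * t2, t_l=1.25 * t2, n=0.0)


@dataclass(frozen=True)
class LineMinimum:
    """One candidate minimum found by the segmented line search."""

    s: float  # position along the segment, in [0, 1]
    point: np.ndarray
    value: float


def segmented_line_search(
    objective: Callable[[np.ndarray], float],
    start: np.ndarray,
    direction: np.ndarray,
    subsegments: int = 20,
    brent_tol: float = 1e-6,
) -> list[LineMinimum]:
    """All local minima of ``objective`` along ``start + s*direction``, s in [0,1].

    The segment is probed at ``subsegments + 1`` equally spaced points.  The
    probe maxima split the segment into unimodal pieces; the interior
    minimum of each piece is refined with Brent's method.  Both endpoints
    are always included as candidates.  Non-finite probe values are treated
    as +inf.  The result is sorted by objective value (best first).
    """
    start = np.asarray(start, dtype=float)
    direction = np.asarray(direction, dtype=float)
    if not np.any(direction != 0):
        raise ValueError("direction must be nonzero")
    m = int(subsegments)
    s_grid = np.arange(m + 1) / m

    def f(s: float) -> float:
        v = objective(start + s * direction)
        return float(v) if np.isfinite(v) else np.inf

    g = np.array([f(s) for s in s_grid])
    maxima = [k for k in range(1, m) if g[k] > g[k - 1] and g[k] > g[k + 1]]
    cuts = [0, *maxima, m]
    found: list[LineMinimum] = [
        LineMinimum(0.0, start.copy(), g[0]),
        LineMinimum(1.0, start + direction, g[m]),
    ]
    for c0, c1 in zip(cuts[:-1], cuts[1:]):
        if c1 - c0 < 2:
            continue
        k = c0 + 1 + int(np.argmin(g[c0 + 1:c1]))
        if not np.isfinite(g[k]):
            continue
        if not (g[k] < g[c0] and g[k] < g[c1]):
            continue  # no strict bracket (e.g. a flat stretch)
        res = optimize.minimize_scalar(
            f,
            bracket=None,
            bounds=(s_grid[k - 1], s_grid[k + 1]),
            method="bounded",
            options={"xatol": brent_tol, "maxiter": 100},
        )
        s_ref = float(res.x)
        f_ref = float(res.fun)
        if g[k] < f_ref:  # keep the better of grid probe and refinement
            s_ref, f_ref = float(s_grid[k]), float(g[k])
        found.append(LineMinimum(s_ref, start + s_ref * direction, f_ref))
    found.sort(key=lambda lm: lm.value)
    return found


def powell_cycle(
    point: np.ndarray,
    directions: Sequence[np.ndarray] | np.ndarray,
    objective: Callable[[np.ndarray], float],
    subsegments: int = 20,
    brent_tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    """One conjugate-direction cycle over the current direction set.

    Each direction ``v`` is minimised bidirectionally (the searched segment
    runs from ``point - v`` to ``point + v``); the accepted scalar moves
    accumulate into a net displacement, which replaces the direction with
    the largest contribution ``|gamma| * ||v||``.

    Returns ``(new_point, new_directions, new_value, displacement)``.
    """
    point = np.asarray(point, dtype=float).copy()
    dirs = np.array(directions, dtype=float).copy()
    if dirs.ndim != 2 or dirs.shape[0] != dirs.shape[1] or dirs.shape[1] != point.size:
        raise ValueError("directions must be a square set matching the point")
    start = point.copy()
    f_cur = float(objective(point))
    contrib = np.zeros(dirs.shape[0])
    for i, v in enumerate(dirs):
        if not np.any(v != 0):
            continue
        minima = segmented_line_search(
            objective, point - v, 2.0 * v, subsegments=subsegments,
            brent_tol=brent_tol,
        )
        best = minima[0]
        if best.value < f_cur:
            gamma = 2.0 * best.s - 1.0
            point = best.point
            f_cur = best.value
            contrib[i] = abs(gamma) * float(np.linalg.norm(v))
    displacement = point - start
    if np.linalg.norm(displacement) > 1e-12:
        dirs[int(np.argmax(contrib))] = displacement
    return point, dirs, f_cur, displacement


def _voxel_seed(seed: int, voxel_index: int = 0) -> np.uint64:
    """Per-voxel RNG stream: the user seed XOR the voxel's flat index."""
    return np.uint64(np.uint64(seed) ^ np.uint64(voxel_index))


def wscd_fit(
    series: EchoSeries,
    weights: np.ndarray | None = None,
    config: WSCDConfig | None = None,
    rng_seed: int | None = None,
    return_trace: bool = False,
) -> FitResult | tuple[FitResult, np.ndarray]:
    """Fit one voxel's decay curve with the WSCD optimiser.

    Parameters
    ----------
    series
        The voxel's echo-time/intensity curve.
    weights
        Per-echo weights W(t); defaults to all ones (unweighted fit).
    config
        Optimiser settings; defaults to :class:`WSCDConfig`.
    rng_seed
        Seed for the stochastic state selection; overrides ``config.seed``.
    return_trace
        Also return the best-objective trace (one value per iteration),
        useful for monotonicity checks.
    """
    cfg = config or WSCDConfig()
    seed = cfg.seed if rng_seed is None else int(rng_seed)
    y = series.intensities
    w = np.ones(series.n_echoes) if weights is None else np.asarray(weights, float)
    if w.shape != series.echo_times.shape:
        raise ValueError("weights length does not match echo count")
    if np.all(y == 0):
        params = BiexpParams(a_s=0.0, a_l=0.0, t_s=CLAMP_T_MAX, t_l=CLAMP_T_MAX)
        result = FitResult(params, 0.0, OutcomeClass.CONSTANT, 0, True)
        return (result, np.zeros(0)) if return_trace else result

    b0 = loglinear_init(series).to_vector()
    lo, hi = param_bounds(y)
    # normalised search space: times in ms, amplitudes/offset in hundredths
    # of the maximum voxel intensity, so one step length fits every axis
    s_a = max(float(np.max(np.abs(y))), 1.0) / 100.0
    scale = np.array([1.0, 1.0, s_a, s_a, s_a])
    trace = np.full(cfg.max_iterations, np.nan)
    best_p, best_f, n_iter, converged = _wscd_core.wscd_kernel(
        series.echo_times, y, w, b0 / scale, scale, float(cfg.initial_step),
        _voxel_seed(seed), cfg.max_iterations, cfg.subsegments, cfg.tol,
        cfg.list_capacity, cfg.brent_tol, cfg.brent_max_iterations,
        lo / scale, hi / scale, trace,
    )
    params = BiexpParams.from_vector(best_p * scale).ordered()
    amp_floor = AMP_FLOOR_FRACTION * float(np.max(np.abs(y)))
    outcome = classify_fit(params, amp_floor=amp_floor)
    result = FitResult(params, float(best_f), outcome, int(n_iter), bool(converged))
    if return_trace:
        return result, trace[:n_iter]
    return result
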