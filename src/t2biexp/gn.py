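"""Non-negative Gauss-Newton reference fitter for the unweighted biexponential.

Fits the four-parameter model ``A_S e^{-t/T_S} + A_L e^{-t/T_L}`` (no
constant offset — any residual noise floor is not modelled) by projected
Gauss-Newton with adaptive Levenberg damping: analytic-Jacobian normal
equations, a damping term that grows until a step decreases the sum of
squares and shrinks after accepted steps, and projection of each iterate
onto the amplitude/time box.  This is the standard reference method the
weighted stochastic fitter is benchmarked against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_model import (
    AMP_FLOOR_FRACTION,
    BiexpParams,
    EchoSeries,
    FitResult,
    OutcomeClass,
    classify_fit,
    param_bounds,
)
from .wscd import loglinear_init

__all__ = ["GNConfig", "gn_fit"]


@dataclass(frozen=True)
class GNConfig:
    """Gauss-Newton settings.

    ``levenberg_lambda`` is the initial damping; it is multiplied by
    ``levenberg_up`` until a step decreases the sum of squares (at most
    ``max_damping_tries`` times per iteration) and by ``levenberg_down``
    after every accepted step.  Iteration stops at ``max_iterations`` or
    when the relative objective decrease falls below ``rel_tol``.
    """

    max_iterations: int = 200
    rel_tol: float = 1e-10
    levenberg_lambda: float = 1e-3
    levenberg_up: float = 10.0
    levenberg_down: float = 0.3
    max_damping_tries: int = 30


def _residual_jacobian(p: np.ndarray, t: np.ndarray, y: np.ndarray):
    """Residual r = model - y and its Jacobian wrt (T_S, T_L, A_S, A_L)."""
    t_s, t_l, a_s, a_l = p
    e_s = np.exp(-t / t_s)
    e_l = np.exp(-t / t_l)
    r = a_s * e_s + a_l * e_l - y
    jac = np.column_stack([
        a_s * e_s * t / (t_s * t_s),
        a_l * e_l * t / (t_l * t_l),
        e_s,
        e_l,
    ])
    return r, jac


def gn_fit(
    series: EchoSeries,
    config: GNConfig | None = None,
    return_trace: bool = False,
    init: BiexpParams | None = None,
) -> FitResult | tuple[FitResult, np.ndarray]:
    """Fit one voxel with projected, damped Gauss-Newton.

    The start point comes from the same log-linear monoexponential recipe
    as the stochastic fitter (offset dropped), unless an explicit ``init``
    is given.  Returns the fit with the
    canonical ``T_S <= T_L`` ordering; with ``return_trace`` also the sum
    of squared residuals after every accepted step (non-increasing by
    construction).
    """
    cfg = config or GNConfig()
    t = series.echo_times
    y = series.intensities
    if series.n_echoes < 4:
        raise ValueError("Gauss-Newton needs at least 4 echoes for 4 parameters")
    if np.all(y == 0):
        params = BiexpParams(a_s=0.0, a_l=0.0, t_s=5000.0, t_l=5000.0)
        result = FitResult(params, 0.0, OutcomeClass.CONSTANT, 0, True)
        return (result, np.zeros(0)) if return_trace else result

    lo5, hi5 = param_bounds(y)
    lo = lo5[:4]
    hi = hi5[:4]
    if init is None:
        init = loglinear_init(series)
    p = np.clip(np.array([init.t_s, init.t_l, init.a_s, init.a_l]), lo, hi)

    r, jac = _residual_jacobian(p, t, y)
    ssr = float(r @ r)
    trace = [ssr]
    lam = cfg.levenberg_lambda
    converged = False
    n_iter = 0
    for it in range(cfg.max_iterations):
        n_iter = it + 1
        jtj = jac.T @ jac
        jtr = jac.T @ r
        damp = np.diag(np.maximum(np.diag(jtj), 1e-12))
        accepted = False
        for _ in range(cfg.max_damping_tries):
            try:
                step = np.linalg.solve(jtj + lam * damp, -jtr)
            except np.linalg.LinAlgError:
                lam *= cfg.levenberg_up
                continue
            if not np.all(np.isfinite(step)):
                lam *= cfg.levenberg_up
                continue
            cand = np.clip(p + step, lo, hi)
            r_c, jac_c = _residual_jacobian(cand, t, y)
            ssr_c = float(r_c @ r_c)
            if ssr_c < ssr:
                accepted = True
                break
            lam *= cfg.levenberg_up
        if not accepted:
            converged = True  # no descent step at any damping: stationary
            break
        rel_drop = (ssr - ssr_c) / max(ssr, 1e-300)
        p, r, jac, ssr = cand, r_c, jac_c, ssr_c
        trace.append(ssr)
        lam = max(lam * cfg.levenberg_down, 1e-12)
        if rel_drop < cfg.rel_tol:
            converged = True
            break

    t_s, t_l, a_s, a_l = p
    params = BiexpParams(a_s=a_s, a_l=a_l, t_s=t_s, t_l=t_l, n=0.0).ordered()
    amp_floor = AMP_FLOOR_FRACTION * float(np.max(np.abs(y)))
    outcome = classify_fit(params, amp_floor=amp_floor)
    result = FitResult(params, ssr, outcome, n_iter, converged)
    if return_trace:
        return result, np.asarray(trace)
    return result
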