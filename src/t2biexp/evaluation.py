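"""Accuracy and goodness-of-fit statistics for reconstructed T2 maps.

Accuracy is assessed on per-voxel differences (estimated minus true
relaxation time) for the short and long components: their mean and sample
standard deviation, the two-sided Wilcoxon signed-rank test of the
differences against zero (with continuity correction in the large-sample
normal approximation, exact enumeration for small samples), and the
Hodges-Lehmann pseudomedian with its 95% signed-rank confidence interval.
Goodness of fit is the per-voxel sum of squared residuals between the
measured and fitted signal; map quality is summarised as the ratio of the
mean map value in a signal region to the mean in a background region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .signal_model import BiexpParams, FitResult, MultiEchoImage, OutcomeClass
from .weighting import WeightMap

__all__ = [
    "AccuracyReport",
    "walsh_averages",
    "pseudomedian_ci",
    "wilcoxon_signed_rank",
    "component_accuracy",
    "accuracy_table",
    "mse_map",
    "map_snr",
]

EXACT_N_MAX = 25  # exact signed-rank distribution up to this sample size


@dataclass(frozen=True)
class AccuracyReport:
    """Accuracy summary for one (component, noise level, method) cell."""

    component: str  # "T_S" or "T_L"
    snr_level: float | None
    method: str
    n: int
    mean_difference: float
    sd: float
    pseudomedian: float
    ci_low: float
    ci_high: float
    p_value: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.pseudomedian <= self.ci_high):
            raise ValueError("CI must bracket the pseudomedian")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value out of [0, 1]")


def walsh_averages(diffs: np.ndarray) -> np.ndarray:
    """All pairwise averages (d_i + d_j)/2 for i <= j, sorted ascending."""
    d = np.sort(np.asarray(diffs, dtype=float))
    iu = np.triu_indices(d.size)
    return np.sort((d[iu[0]] + d[iu[1]]) / 2.0)


def _signed_rank_lower_quantile(n: int, alpha: float) -> int:
    """Largest k with P(W <= k) <= alpha under the null signed-rank law.

    Exact by dynamic programming for n <= EXACT_N_MAX, else the normal
    approximation with continuity correction.
    """
    if n <= EXACT_N_MAX:
        total = n * (n + 1) // 2
        counts = np.zeros(total + 1)
        counts[0] = 1.0
        for i in range(1, n + 1):
            counts[i:] = counts[i:] + counts[:total + 1 - i]
        cdf = np.cumsum(counts) / 2.0**n
        k = int(np.searchsorted(cdf, alpha, side="right")) - 1
        return max(k, -1)
    mu = n * (n + 1) / 4.0
    sd = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
    z = stats.norm.ppf(alpha)
    return max(int(np.floor(mu + z * sd - 0.5)), -1)


def pseudomedian_ci(
    diffs: np.ndarray, confidence: float = 0.95
) -> tuple[float, float, float]:
    """Hodges-Lehmann pseudomedian and signed-rank confidence interval.

    The pseudomedian is the median of the Walsh averages; the interval is
    the standard one read off the ordered Walsh averages at the
    signed-rank critical ranks.
    """
    d = np.asarray(diffs, dtype=float)
    if d.size == 0:
        raise ValueError("empty difference set")
    ws = walsh_averages(d)
    pm = float(np.median(ws))
    alpha = (1.0 - confidence) / 2.0
    k = _signed_rank_lower_quantile(d.size, alpha)
    # CI endpoints are the Walsh-average order statistics at the signed-rank
    # critical ranks: [ws_(q), ws_(M+1-q)] with q = k+1 (1-indexed, q >= 1)
    m_total = ws.size
    lo_idx = min(max(k, 0), m_total - 1)
    hi_idx = max(m_total - 1 - lo_idx, lo_idx)
    lo = float(ws[lo_idx])
    hi = float(ws[hi_idx])
    return pm, min(lo, pm), max(hi, pm)


def wilcoxon_signed_rank(diffs: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p-value of the differences vs zero.

    Zero differences are dropped; the exact distribution is used for small
    tie-free samples, otherwise the normal approximation with continuity
    correction.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    ranks_tied = np.unique(np.abs(d)).size < d.size
    if d.size <= EXACT_N_MAX and not ranks_tied:
        method = "exact"
    else:
        method = "approx"
    res = stats.wilcoxon(
        d, zero_method="wilcox", correction=True, alternative="two-sided",
        method=method,
    )
    return float(res.pvalue)


def component_accuracy(
    diffs: np.ndarray,
    component: str,
    method: str = "",
    snr_level: float | None = None,
) -> AccuracyReport:
    """Full accuracy summary of one difference sample."""
    d = np.asarray(diffs, dtype=float)
    if d.size == 0:
        raise ValueError("empty voxel set")
    pm, lo, hi = pseudomedian_ci(d)
    sd = float(np.std(d, ddof=1)) if d.size > 1 else 0.0
    return AccuracyReport(
        component=component,
        snr_level=snr_level,
        method=method,
        n=int(d.size),
        mean_difference=float(np.mean(d)),
        sd=sd,
        pseudomedian=pm,
        ci_low=lo,
        ci_high=hi,
        p_value=wilcoxon_signed_rank(d),
    )


def accuracy_table(
    fits: Sequence[FitResult],
    truth: Sequence[BiexpParams],
    method: str = "",
    snr_level: float | None = None,
    include_degenerate: bool = False,
    t_inf_threshold: float = 1000.0,
    amp_floor: float = 0.0,
) -> pd.DataFrame:
    """Accuracy table (one row per component) for a set of fitted voxels.

    A voxel contributes an ``estimated - true`` difference for a component
    only when the fit actually extracted that component: its relaxation
    time below ``t_inf_threshold`` (a time driven to the clamp box carries
    no information) and its amplitude at least ``amp_floor``.  Voxels whose
    fit degenerated to a constant are excluded entirely.  With
    ``include_degenerate`` every voxel contributes both components.
    """
    if len(fits) != len(truth):
        raise ValueError("fits and truth must align on the same voxel set")
    if len(fits) == 0:
        raise ValueError("empty voxel set")

    def _usable(f: FitResult, t2: float, amp: float) -> bool:
        if include_degenerate:
            return True
        if f.outcome_class is OutcomeClass.CONSTANT:
            return False
        return t2 <= t_inf_threshold and amp >= amp_floor

    d_ts = np.array(
        [f.params.t_s - tr.t_s for f, tr in zip(fits, truth)
         if _usable(f, f.params.t_s, f.params.a_s)]
    )
    d_tl = np.array(
        [f.params.t_l - tr.t_l for f, tr in zip(fits, truth)
         if _usable(f, f.params.t_l, f.params.a_l)]
    )
    if d_ts.size == 0 or d_tl.size == 0:
        raise ValueError("no usable voxels (all fits degenerate)")
    rows = [
        component_accuracy(d_ts, "T_S", method=method, snr_level=snr_level),
        component_accuracy(d_tl, "T_L", method=method, snr_level=snr_level),
    ]
    return pd.DataFrame(
        {
            "component": [r.component for r in rows],
            "snr": [r.snr_level for r in rows],
            "method": [r.method for r in rows],
            "n": [r.n for r in rows],
            "mean_diff": [r.mean_difference for r in rows],
            "sd": [r.sd for r in rows],
            "pseudomedian": [r.pseudomedian for r in rows],
            "ci_low": [r.ci_low for r in rows],
            "ci_high": [r.ci_high for r in rows],
            "p": [r.p_value for r in rows],
        }
    )


def mse_map(
    image: MultiEchoImage,
    params_maps: dict[str, np.ndarray],
    weights: WeightMap | None = None,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, float, float]:
    """Per-voxel sum of squared residuals at the fitted parameters.

    ``params_maps`` holds grids ``t_s, t_l, a_s, a_l, n`` (NaN where
    unfitted).  With a weight map the weighted model is evaluated, matching
    the objective the weighted fitter minimised; otherwise weights are 1.
    Returns the grid plus mean and sample SD over the mask.
    """
    y = image.data
    te = image.echo_times
    w = weights.weights if weights is not None else np.ones_like(y)
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        model = (
            w * params_maps["a_s"][:, :, None]
            * np.exp(-te[None, None, :] / params_maps["t_s"][:, :, None])
            + w * params_maps["a_l"][:, :, None]
            * np.exp(-te[None, None, :] / params_maps["t_l"][:, :, None])
            + params_maps["n"][:, :, None]
        )
        grid = np.sum((model - y) ** 2, axis=2)
    if mask is None:
        mask = np.isfinite(grid)
    else:
        mask = np.asarray(mask, dtype=bool) & np.isfinite(grid)
    vals = grid[mask]
    if vals.size == 0:
        raise ValueError("empty mask")
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return grid, float(np.mean(vals)), sd


def map_snr(
    t2_map: np.ndarray, signal_mask: np.ndarray, background_mask: np.ndarray
) -> float:
    """Map SNR: mean over the signal region divided by mean over background."""
    signal_mask = np.asarray(signal_mask, dtype=bool)
    background_mask = np.asarray(background_mask, dtype=bool)
    if not signal_mask.any() or not background_mask.any():
        raise ValueError("masks must be non-empty")
    if np.any(signal_mask & background_mask):
        raise ValueError("masks must be disjoint")
    signal = float(np.nanmean(t2_map[signal_mask]))
    noise = float(np.nanmean(t2_map[background_mask]))
    if noise == 0.0:
        warnings.warn("background mean is zero; map SNR is infinite")
        return np.inf
    return signal / noise
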