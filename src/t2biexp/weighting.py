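"""Neighbourhood-based per-voxel, per-echo weights for the fitting objective.

For each voxel P the weights compare P's intensity with every neighbour Q in
a ``(2r+1) x (2r+1)`` window, echo by echo.  A pair contributes a similarity
factor

    alpha_{P,Q}(t) = exp(-||P-Q||^2 / sigma^2) * exp(-(y_P(t)-y_Q(t))^2 / sigma^2)

and an intensity-ratio normalisation factor ``omega_{P,Q}(t) = y_Q(t)/y_P(t)``,
where ``sigma^2`` is the local sample variance of the intensities in P's
window at echo t (the local noise measure).  The weight of echo t at P is

    W_P(t) = n_TE * sum_Q alpha * omega / sum_t sum_Q alpha

so that echoes whose neighbourhood looks consistent (low local noise) are
promoted relative to noisier ones.  On a spatially constant image every
omega is 1 and every alpha is equal across echoes, so W collapses to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .signal_model import MultiEchoImage

__all__ = [
    "VARIANCE_FLOOR",
    "WeightMap",
    "local_noise_variance",
    "pair_factors",
    "compute_weights",
]

VARIANCE_FLOOR = 1e-6  # floor for the local variance (avoids division by zero)
INTENSITY_EPS = 1e-12  # y_P at or below this gets a neutral omega = 1


@dataclass(frozen=True)
class WeightMap:
    """Per-voxel, per-echo weights with the inputs used to build them."""

    weights: np.ndarray  # (rows, cols, n_echoes)
    radius: int
    sigma_sq: np.ndarray  # (rows, cols, n_echoes) local noise variances

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.weights)) or np.any(self.weights < 0):
            raise ValueError("weights must be finite and non-negative")

    def at(self, row: int, col: int) -> np.ndarray:
        return self.weights[row, col, :]


def local_noise_variance(
    image: MultiEchoImage, radius: int, floor: float = VARIANCE_FLOOR
) -> np.ndarray:
    """Windowed sample variance of each echo image (population divisor).

    The window is the ``(2r+1) x (2r+1)`` square centred on each voxel,
    clipped at the image borders (the divisor is the number of in-image
    pixels).  Results are floored at ``floor``.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    rows, cols = image.shape
    size = 2 * radius + 1
    if rows * cols < size * size:
        raise ValueError(
            f"image ({rows}x{cols}) smaller than the {size}x{size} window"
        )
    y = image.data
    # Clipped-window means via zero-padded box sums divided by in-image counts.
    kw = {"size": (size, size, 1), "mode": "constant", "cval": 0.0}
    area = float(size * size)
    counts = ndimage.uniform_filter(np.ones(y.shape), **kw) * area
    mean = ndimage.uniform_filter(y, **kw) * area / counts
    mean_sq = ndimage.uniform_filter(y * y, **kw) * area / counts
    var = mean_sq - mean * mean
    return np.maximum(var, floor)


def pair_factors(
    y_p: float, y_q: float, dist: float, sigma_sq: float
) -> tuple[float, float]:
    """Similarity factor alpha and normalisation factor omega for one (P, Q) pair.

    Parameters
    ----------
    y_p, y_q
        Intensities at the centre voxel P and neighbour Q for one echo.
    dist
        Euclidean pixel distance between P and Q.
    sigma_sq
        Local noise variance at (P, echo).
    """
    if sigma_sq <= 0:
        raise ValueError("sigma_sq must be positive")
    alpha = float(np.exp(-(dist * dist) / sigma_sq) * np.exp(-((y_p - y_q) ** 2) / sigma_sq))
    omega = 1.0 if y_p <= INTENSITY_EPS else float(y_q / y_p)
    return alpha, omega


def compute_weights(
    image: MultiEchoImage, radius: int = 2, variance_floor: float = VARIANCE_FLOOR
) -> WeightMap:
    """Build the full per-voxel, per-echo weight map for an image stack."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    rows, cols = image.shape
    if rows * cols < 2:
        raise ValueError("image has no neighbourhood (need at least 2 pixels)")
    sigma_sq = local_noise_variance(image, radius, floor=variance_floor)
    weights = _weights_impl(image.data, sigma_sq, radius)
    return WeightMap(weights=weights, radius=radius, sigma_sq=sigma_sq)


def _weights_impl(
    y: np.ndarray, sigma_sq: np.ndarray, radius: int, unit_omega: bool = False
) -> np.ndarray:
    """Accumulate alpha/omega sums over all window offsets (vectorised).

    ``unit_omega`` substitutes omega = 1 for every pair; with that
    substitution the weights of each voxel average to exactly 1 over echoes
    (used to verify the normalisation identity).
    """
    rows, cols, n_te = y.shape
    num = np.zeros_like(y)  # sum_Q alpha * omega, per echo
    den = np.zeros_like(y)  # sum_Q alpha, per echo
    for di in range(-radius, radius + 1):
        for dj in range(-radius, radius + 1):
            if di == 0 and dj == 0:
                continue
            # P-index ranges for which Q = P + (di, dj) is inside the image
            p_r = slice(max(0, -di), rows - max(0, di))
            p_c = slice(max(0, -dj), cols - max(0, dj))
            q_r = slice(max(0, di), rows + min(0, di))
            q_c = slice(max(0, dj), cols + min(0, dj))
            y_p = y[p_r, p_c, :]
            y_q = y[q_r, q_c, :]
            s2 = sigma_sq[p_r, p_c, :]
            dist_sq = float(di * di + dj * dj)
            # floor keeps the algebra alive when every exponent underflows
            # (e.g. spatially constant images, where all alphas cancel)
            alpha = np.maximum(
                np.exp(-dist_sq / s2) * np.exp(-((y_p - y_q) ** 2) / s2), 1e-280
            )
            if unit_omega:
                omega = 1.0
            else:
                omega = np.where(y_p > INTENSITY_EPS, y_q / np.where(
                    y_p > INTENSITY_EPS, y_p, 1.0), 1.0)
            num[p_r, p_c, :] += alpha * omega
            den[p_r, p_c, :] += alpha
    den_total = den.sum(axis=2, keepdims=True)  # sum over echoes and neighbours
    if np.any(den_total <= 0):
        raise ValueError("empty neighbourhood: no in-image neighbours found")
    return n_te * num / den_total
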