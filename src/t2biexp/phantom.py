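"""Synthetic multi-echo phantoms with known biexponential ground truth.

The default phantom is a 100 x 100 image tiled into 25 subimages of
20 x 20 pixels; every subimage carries one (T_S, T_L) combination from
T_S in {5,...,25} ms and T_L in {40,...,80} ms at fixed amplitudes
A_S = 1200 and A_L = 1800, sampled at eight echo times 9, 18, ..., 72 ms.
Noise of standard deviation sigma is added per pixel and echo: plain
Gaussian noise when the phantom-level SNR = (A_S + A_L)/sigma is at least
7, and Rician magnitude noise (the magnitude of a complex Gaussian
perturbation) below that, matching how magnitude MRI behaves at low SNR.
The default sigma levels 50, 75, 150, 300 and 600 give SNR 60, 40, 20,
10 and 5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal_model import BiexpParams, MultiEchoImage

__all__ = [
    "GAUSSIAN_SNR_THRESHOLD",
    "DEFAULT_SIGMAS",
    "PhantomSpec",
    "Phantom",
    "build_phantom",
    "add_noise",
]

GAUSSIAN_SNR_THRESHOLD = 7.0  # Gaussian noise at or above, Rician below
DEFAULT_SIGMAS = (50.0, 75.0, 150.0, 300.0, 600.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Phantom geometry, true parameters and noise level."""

    grid_size: int = 100
    subgrid: int = 5
    echo_times: tuple[float, ...] = (9.0, 18.0, 27.0, 36.0, 45.0, 54.0, 63.0, 72.0)
    a_s_true: float = 1200.0
    a_l_true: float = 1800.0
    t_s_values: tuple[float, ...] = (5.0, 10.0, 15.0, 20.0, 25.0)
    t_l_values: tuple[float, ...] = (40.0, 50.0, 60.0, 70.0, 80.0)
    sigma: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_size % self.subgrid != 0:
            raise ValueError("grid_size must be divisible by subgrid")
        if len(self.t_s_values) * len(self.t_l_values) != self.subgrid**2:
            raise ValueError(
                "need len(t_s_values) * len(t_l_values) == subgrid**2 so each "
                "subimage gets a unique (T_S, T_L) pair"
            )
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @property
    def snr(self) -> float:
        """Phantom-level SNR: amplitude sum over noise standard deviation."""
        return (self.a_s_true + self.a_l_true) / self.sigma

    @property
    def subimage_size(self) -> int:
        return self.grid_size // self.subgrid


@dataclass
class Phantom:
    """A noisy phantom stack together with its per-voxel ground truth."""

    image: MultiEchoImage
    truth_t_s: np.ndarray
    truth_t_l: np.ndarray
    truth_a_s: np.ndarray
    truth_a_l: np.ndarray
    snr: float
    spec: PhantomSpec = field(repr=False, default=None)

    def truth_at(self, row: int, col: int) -> BiexpParams:
        return BiexpParams(
            a_s=float(self.truth_a_s[row, col]),
            a_l=float(self.truth_a_l[row, col]),
            t_s=float(self.truth_t_s[row, col]),
            t_l=float(self.truth_t_l[row, col]),
        )


def add_noise(
    signal: np.ndarray, sigma: float, snr: float, rng: np.random.Generator
) -> np.ndarray:
    """Add measurement noise to a noiseless signal grid.

    For ``snr`` >= 7 the noise is additive Gaussian with SD ``sigma``
    (negative outputs are possible and kept).  Below that the output is the
    Rician magnitude ``sqrt((signal + g1)^2 + g2^2)`` with independent
    Gaussian ``g1, g2`` of SD ``sigma``, which is non-negative by
    construction.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    signal = np.asarray(signal, dtype=float)
    if snr >= GAUSSIAN_SNR_THRESHOLD:
        return signal + rng.normal(0.0, sigma, size=signal.shape)
    g1 = rng.normal(0.0, sigma, size=signal.shape)
    g2 = rng.normal(0.0, sigma, size=signal.shape)
    return np.sqrt((signal + g1) ** 2 + g2**2)


def build_phantom(spec: PhantomSpec | None = None, noiseless: bool = False) -> Phantom:
    """Build the tiled biexponential phantom described by ``spec``.

    Subimages are assigned (T_S, T_L) pairs in row-major order of the
    Cartesian product of the sorted value lists; the top-left subimage gets
    the first T_S with the first T_L.  With ``noiseless=True`` the clean
    signal stack is returned (useful for parameter-recovery checks).
    """
    spec = spec or PhantomSpec()
    n = spec.grid_size
    sub = spec.subimage_size
    pairs = [(ts, tl) for ts in spec.t_s_values for tl in spec.t_l_values]
    truth_t_s = np.empty((n, n))
    truth_t_l = np.empty((n, n))
    for si in range(spec.subgrid):
        for sj in range(spec.subgrid):
            ts, tl = pairs[si * spec.subgrid + sj]
            truth_t_s[si * sub:(si + 1) * sub, sj * sub:(sj + 1) * sub] = ts
            truth_t_l[si * sub:(si + 1) * sub, sj * sub:(sj + 1) * sub] = tl
    truth_a_s = np.full((n, n), spec.a_s_true)
    truth_a_l = np.full((n, n), spec.a_l_true)

    te = np.asarray(spec.echo_times)
    clean = (
        truth_a_s[:, :, None] * np.exp(-te[None, None, :] / truth_t_s[:, :, None])
        + truth_a_l[:, :, None] * np.exp(-te[None, None, :] / truth_t_l[:, :, None])
    )
    if noiseless:
        data = clean
    else:
        rng = np.random.default_rng(spec.seed)
        data = add_noise(clean, spec.sigma, spec.snr, rng)
    image = MultiEchoImage(data=data, echo_times=te)
    return Phantom(
        image=image,
        truth_t_s=truth_t_s,
        truth_t_l=truth_t_l,
        truth_a_s=truth_a_s,
        truth_a_l=truth_a_l,
        snr=spec.snr,
        spec=spec,
    )
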