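"""Biexponential decay model, weighted least-squares objective and fit classification.

The transverse-relaxation signal of a two-compartment voxel measured at echo
time ``t`` (ms) is modelled as

    f(t) = A_S * exp(-t / T_S) + A_L * exp(-t / T_L) + n

with a short component ``(A_S, T_S)``, a long component ``(A_L, T_L)`` and a
constant offset ``n`` absorbing the mean noise level.  The weighted objective
minimised per voxel multiplies each exponential term by a per-echo weight
``W(t)`` (see :mod:`t2biexp.weighting`); the offset is left unweighted.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CLAMP_T_MIN",
    "CLAMP_T_MAX",
    "T_INF_THRESHOLD",
    "AMP_FLOOR_FRACTION",
    "DISTINCTNESS_RATIO",
    "OutcomeClass",
    "EchoSeries",
    "BiexpParams",
    "FitResult",
    "MultiEchoImage",
    "biexp_signal",
    "weighted_objective",
    "classify_fit",
    "param_bounds",
]

# Box constraints applied to the parameter vector during optimisation.
# Relaxation times are clamped to a physically plausible range; amplitudes
# and offset are bounded relative to the observed voxel intensities.
CLAMP_T_MIN = 0.1  # ms
CLAMP_T_MAX = 5000.0  # ms
AMP_CLAMP_FACTOR = 10.0  # A in [0, 10 * max |y|]

# Fit-outcome classification defaults: a relaxation time above the
# "infinity" threshold or an amplitude below the floor means the component
# carries no information; two finite components must also be distinct.
T_INF_THRESHOLD = 1000.0  # ms
AMP_FLOOR_FRACTION = 0.01  # fraction of the voxel's maximum intensity
DISTINCTNESS_RATIO = 1.05  # minimum T_L / T_S for a genuine biexponential


class OutcomeClass(enum.Enum):
    """The three qualitative outcomes of a per-voxel biexponential fit.

    ``BIEXPONENTIAL``  — both relaxation times extracted (two distinct,
    finite components with non-negligible amplitudes).
    ``MONOEXPONENTIAL`` — only one effective component, or two components
    with indistinguishable relaxation times.
    ``CONSTANT`` — the best fit degenerates to a constant (both times
    effectively infinite, or both amplitudes negligible).
    """

    BIEXPONENTIAL = "biexponential"
    MONOEXPONENTIAL = "monoexponential"
    CONSTANT = "constant"


@dataclass(frozen=True)
class EchoSeries:
    """One voxel's decay curve: echo times (ms) paired with magnitudes."""

    echo_times: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        te = np.asarray(self.echo_times, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if te.ndim != 1 or y.ndim != 1:
            raise ValueError("echo_times and intensities must be 1-D")
        if te.size != y.size:
            raise ValueError(
                f"echo_times ({te.size}) and intensities ({y.size}) differ in length"
            )
        if te.size < 2:
            raise ValueError("need at least two echoes")
        if not (np.all(np.diff(te) > 0) and te[0] > 0):
            raise ValueError("echo_times must be positive and strictly increasing")
        object.__setattr__(self, "echo_times", te)
        object.__setattr__(self, "intensities", y)

    @property
    def n_echoes(self) -> int:
        return int(self.echo_times.size)


@dataclass(frozen=True)
class BiexpParams:
    """One voxel's biexponential parameter vector.

    Attributes
    ----------
    a_s, a_l
        Short- and long-component amplitudes (signal units, >= 0).
    t_s, t_l
        Short and long relaxation times (ms, > 0).
    n
        Constant signal offset (signal units).
    """

    a_s: float
    a_l: float
    t_s: float
    t_l: float
    n: float = 0.0

    def __post_init__(self) -> None:
        if self.t_s <= 0 or self.t_l <= 0:
            raise ValueError("relaxation times must be positive")
        if self.a_s < 0 or self.a_l < 0:
            raise ValueError("amplitudes must be non-negative")

    def ordered(self) -> "BiexpParams":
        """Canonical form with ``t_s <= t_l`` (components swapped if needed)."""
        if self.t_s <= self.t_l:
            return self
        return BiexpParams(
            a_s=self.a_l, a_l=self.a_s, t_s=self.t_l, t_l=self.t_s, n=self.n
        )

    def to_vector(self) -> np.ndarray:
        """Pack as the optimiser's (T_S, T_L, A_S, A_L, n) vector."""
        return np.array([self.t_s, self.t_l, self.a_s, self.a_l, self.n])

    @classmethod
    def from_vector(cls, vec: np.ndarray) -> "BiexpParams":
        t_s, t_l, a_s, a_l, n = (float(v) for v in vec)
        return cls(a_s=a_s, a_l=a_l, t_s=t_s, t_l=t_l, n=n)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a single-voxel fit."""

    params: BiexpParams
    objective: float
    outcome_class: OutcomeClass
    iterations: int
    converged: bool

    def __post_init__(self) -> None:
        if self.objective < 0:
            raise ValueError("objective must be non-negative")
        if self.iterations < 0:
            raise ValueError("iteration count must be non-negative")


@dataclass
class MultiEchoImage:
    """A 2-D grid of decay curves: one image per echo time.

    ``data`` has shape ``(rows, cols, n_echoes)``; ``mask`` (optional) is a
    boolean grid selecting the voxels to fit.
    """

    data: np.ndarray
    echo_times: np.ndarray
    mask: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.echo_times = np.asarray(self.echo_times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (rows, cols, n_echoes)")
        if self.echo_times.ndim != 1 or self.echo_times.size != self.data.shape[2]:
            raise ValueError(
                f"echo axis ({self.data.shape[2]}) does not match "
                f"echo_times ({self.echo_times.size})"
            )
        if not (np.all(np.diff(self.echo_times) > 0) and self.echo_times[0] > 0):
            raise ValueError("echo_times must be positive and strictly increasing")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape[:2]:
                raise ValueError("mask shape does not match image grid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    @property
    def n_echoes(self) -> int:
        return int(self.data.shape[2])

    def series_at(self, row: int, col: int) -> EchoSeries:
        return EchoSeries(self.echo_times, self.data[row, col, :])


def biexp_signal(params: BiexpParams, t: float | np.ndarray) -> float | np.ndarray:
    """Noiseless biexponential model value at echo time(s) ``t`` (ms)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("echo time must be non-negative")
    out = (
        params.a_s * np.exp(-t / params.t_s)
        + params.a_l * np.exp(-t / params.t_l)
        + params.n
    )
    return float(out) if out.ndim == 0 else out


def weighted_objective(
    params: BiexpParams, series: EchoSeries, weights: np.ndarray
) -> float:
    """Weighted sum of squared residuals for one voxel.

    Each exponential term is scaled by the per-echo weight; the constant
    offset ``n`` enters unweighted:

        g = sum_t [ W(t) A_S e^{-t/T_S} + W(t) A_L e^{-t/T_L} + n - y(t) ]^2
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != series.echo_times.shape:
        raise ValueError(
            f"weights length ({w.size}) does not match echo count "
            f"({series.n_echoes})"
        )
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    t = series.echo_times
    model = (
        w * params.a_s * np.exp(-t / params.t_s)
        + w * params.a_l * np.exp(-t / params.t_l)
        + params.n
    )
    r = model - series.intensities
    return float(np.dot(r, r))


def classify_fit(
    params: BiexpParams,
    t_inf_threshold: float = T_INF_THRESHOLD,
    amp_floor: float = 0.0,
    distinctness_ratio: float = DISTINCTNESS_RATIO,
) -> OutcomeClass:
    """Classify a fitted parameter set as biexponential, monoexponential or constant.

    A component is "effective" when its amplitude reaches ``amp_floor`` and
    its relaxation time stays below ``t_inf_threshold``.  Two effective
    components whose times differ by at least ``distinctness_ratio`` give a
    biexponential outcome; exactly one effective component (or two with
    indistinct times) gives a monoexponential outcome; none gives a constant.
    """
    if t_inf_threshold <= 0:
        raise ValueError("t_inf_threshold must be positive")
    if amp_floor < 0:
        raise ValueError("amp_floor must be non-negative")
    p = params.ordered()
    short_ok = p.a_s >= amp_floor and p.t_s <= t_inf_threshold
    long_ok = p.a_l >= amp_floor and p.t_l <= t_inf_threshold
    n_effective = int(short_ok) + int(long_ok)
    if n_effective == 0:
        return OutcomeClass.CONSTANT
    if n_effective == 1:
        return OutcomeClass.MONOEXPONENTIAL
    if p.t_l / p.t_s >= distinctness_ratio:
        return OutcomeClass.BIEXPONENTIAL
    return OutcomeClass.MONOEXPONENTIAL


def param_bounds(intensities: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Box constraints for the (T_S, T_L, A_S, A_L, n) vector of one voxel."""
    y_max = float(np.max(np.abs(intensities)))
    y_max = max(y_max, 1.0)  # degenerate all-zero voxel: keep a unit box
    lo = np.array([CLAMP_T_MIN, CLAMP_T_MIN, 0.0, 0.0, -y_max])
    hi = np.array(
        [CLAMP_T_MAX, CLAMP_T_MAX, AMP_CLAMP_FACTOR * y_max, AMP_CLAMP_FACTOR * y_max, y_max]
    )
    return lo, hi
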