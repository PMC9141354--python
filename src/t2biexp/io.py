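"""NIfTI-1 reading/writing, whole-image fitting and provenance records.

Multi-echo stacks travel as one 3-D NIfTI-1 volume (rows x cols x echoes)
with a JSON sidecar carrying the echo times (NIfTI has no standard
per-volume echo-time field).  Fitted parameter maps are written one NIfTI
volume per parameter plus an integer outcome-class map, with a provenance
JSON recording the configuration and seed of the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from . import __version__
from .gn import GNConfig, gn_fit
from .signal_model import EchoSeries, MultiEchoImage, OutcomeClass
from .weighting import WeightMap, compute_weights
from .wscd import WSCDConfig, wscd_fit

__all__ = [
    "RunConfig",
    "FitMaps",
    "OUTCOME_CODES",
    "read_multiecho",
    "write_multiecho",
    "read_map",
    "write_map",
    "fit_image",
    "write_fit_maps",
    "read_fit_maps",
]

logger = logging.getLogger(__name__)

OUTCOME_CODES = {
    OutcomeClass.CONSTANT: 0,
    OutcomeClass.MONOEXPONENTIAL: 1,
    OutcomeClass.BIEXPONENTIAL: 2,
}
UNFITTED_CODE = -1

_MAP_NAMES = ("t_s", "t_l", "a_s", "a_l", "n")


@dataclass(frozen=True)
class RunConfig:
    """Settings of one reconstruction run."""

    method: str = "wscd"  # "wscd" or "gn"
    window_radius: int = 2
    seed: int = 0
    wscd: WSCDConfig = field(default_factory=WSCDConfig)
    gn: GNConfig = field(default_factory=GNConfig)

    def __post_init__(self) -> None:
        if self.method not in ("wscd", "gn"):
            raise ValueError(f"unknown method {self.method!r}; use 'wscd' or 'gn'")
        if self.window_radius < 1:
            raise ValueError("window_radius must be >= 1")


@dataclass
class FitMaps:
    """Per-voxel results of a whole-image fit (NaN / -1 where unfitted)."""

    t_s: np.ndarray
    t_l: np.ndarray
    a_s: np.ndarray
    a_l: np.ndarray
    n: np.ndarray
    objective: np.ndarray
    outcome: np.ndarray  # int codes, see OUTCOME_CODES
    iterations: np.ndarray

    def params_maps(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in _MAP_NAMES}


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_multiecho(
    path: str | Path, image: MultiEchoImage, extra: dict | None = None
) -> Path:
    """Write a multi-echo stack as NIfTI-1 plus a JSON echo-time sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(image.data.astype(np.float64), np.eye(4)), str(path))
    sidecar = {"echo_times": [float(t) for t in image.echo_times]}
    if extra:
        sidecar.update(extra)
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def read_multiecho(
    path: str | Path,
    sidecar: str | Path | None = None,
    mask_path: str | Path | None = None,
) -> MultiEchoImage:
    """Read a multi-echo NIfTI-1 stack; echo times come from the sidecar."""
    path = Path(path)
    sidecar = _sidecar_path(path) if sidecar is None else Path(sidecar)
    data = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    if data.ndim != 3 or data.shape[2] < 2:
        raise ValueError("volume must be rows x cols x echoes with >= 2 echoes")
    meta = json.loads(sidecar.read_text())
    echo_times = np.asarray(meta["echo_times"], dtype=float)
    if echo_times.size != data.shape[2]:
        raise ValueError(
            f"echo-count mismatch: volume has {data.shape[2]} echoes but the "
            f"sidecar lists {echo_times.size} echo times"
        )
    mask = None
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    return MultiEchoImage(data=data, echo_times=echo_times, mask=mask)


def write_map(path: str | Path, grid: np.ndarray) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(grid, dtype=np.float64), np.eye(4)), str(path))
    return path


def read_map(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=float)


def fit_image(
    image: MultiEchoImage,
    config: RunConfig | None = None,
    weights: WeightMap | None = None,
) -> FitMaps:
    """Fit every in-mask voxel of the stack independently.

    For the weighted stochastic method the weight map is computed once from
    the full image (or taken from ``weights``); each voxel is then fitted
    on its own, with a per-voxel RNG stream derived as seed XOR flat voxel
    index, so any sub-mask reproduces exactly the values of a full run.
    """
    config = config or RunConfig()
    rows, cols = image.shape
    mask = image.mask if image.mask is not None else np.ones((rows, cols), bool)
    if not mask.any():
        raise ValueError("empty mask: nothing to fit")
    if config.method == "wscd" and weights is None:
        weights = compute_weights(image, radius=config.window_radius)
    shape = (rows, cols)
    maps = FitMaps(
        t_s=np.full(shape, np.nan),
        t_l=np.full(shape, np.nan),
        a_s=np.full(shape, np.nan),
        a_l=np.full(shape, np.nan),
        n=np.full(shape, np.nan),
        objective=np.full(shape, np.nan),
        outcome=np.full(shape, UNFITTED_CODE, dtype=np.int32),
        iterations=np.zeros(shape, dtype=np.int32),
    )
    n_voxels = int(mask.sum())
    logger.info("fitting %d voxels with %s", n_voxels, config.method)
    done = 0
    for r, c in zip(*np.nonzero(mask)):
        series = EchoSeries(image.echo_times, image.data[r, c, :])
        if config.method == "wscd":
            fit = wscd_fit(
                series,
                weights.at(r, c),
                config.wscd,
                rng_seed=config.seed ^ (r * cols + c),
            )
        else:
            fit = gn_fit(series, config.gn)
        p = fit.params
        maps.t_s[r, c] = p.t_s
        maps.t_l[r, c] = p.t_l
        maps.a_s[r, c] = p.a_s
        maps.a_l[r, c] = p.a_l
        maps.n[r, c] = p.n
        maps.objective[r, c] = fit.objective
        maps.outcome[r, c] = OUTCOME_CODES[fit.outcome_class]
        maps.iterations[r, c] = fit.iterations
        done += 1
        if done % 2000 == 0:
            logger.info("  %d / %d voxels", done, n_voxels)
    return maps


def _config_record(config: RunConfig) -> dict:
    rec = dataclasses.asdict(config)
    rec["version"] = __version__
    return rec


def write_fit_maps(out_dir: str | Path, maps: FitMaps, config: RunConfig) -> Path:
    """Write the five parameter maps, the outcome map and a provenance record."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name in _MAP_NAMES + ("objective",):
        write_map(out_dir / f"{name}.nii.gz", getattr(maps, name))
    nib.save(
        nib.Nifti1Image(maps.outcome.astype(np.int32), np.eye(4)),
        str(out_dir / "outcome.nii.gz"),
    )
    (out_dir / "provenance.json").write_text(json.dumps(_config_record(config), indent=2))
    return out_dir


def read_fit_maps(out_dir: str | Path) -> FitMaps:
    out_dir = Path(out_dir)
    kwargs = {
        name: read_map(out_dir / f"{name}.nii.gz")
        for name in _MAP_NAMES + ("objective",)
    }
    outcome = np.asarray(
        nib.load(str(out_dir / "outcome.nii.gz")).dataobj
    ).astype(np.int32)
    return FitMaps(
        outcome=outcome, iterations=np.zeros_like(outcome), **kwargs
    )
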