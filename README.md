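# t2biexp

Voxelwise **biexponential T2 mapping** for multi-echo magnitude MRI.

Quantitative T2 maps assign each image voxel the transverse relaxation
time(s) of its tissue. In heterogeneous musculoskeletal tissue — healing
tendon is the motivating case — a single exponential is too coarse: the
signal at echo time `t` is better described by two compartments,

    f(t) = A_S·exp(−t/T_S) + A_L·exp(−t/T_L) + n,

with a short component (`A_S`, `T_S`) and a long component (`A_L`, `T_L`)
plus a constant noise offset `n`. Separating two decays from a handful of
noisy echoes is badly conditioned, which is where the two fitters in this
package differ:

* **WSCD** — a *weighted stochastic conjugate-direction* fitter: a
  derivative-free search (segmented bidirectional line searches with
  Brent refinement, Powell-style direction replacement, and a stochastic
  list of candidate states that re-expands alternative local minima),
  minimising a per-voxel objective whose exponential terms are scaled by
  neighbourhood-derived per-echo weights
  `W_P(t) = n_TE · Σ_Q α_{P,Q}ω_{P,Q} / Σ_t Σ_Q α_{P,Q}`.
* **GN** — the reference method: projected, damped Gauss–Newton on the
  four-parameter model (no offset), as used by standard radiological
  workstations.

The package also ships the synthetic phantom used to benchmark both
fitters (a 100×100 grid of 25 tiles covering `T_S ∈ {5..25}` ms ×
`T_L ∈ {40..80}` ms at eight echo times, with Gaussian or Rician noise),
and the accuracy statistics: mean/SD of estimated−true differences,
Wilcoxon signed-rank tests with continuity correction, and Hodges–Lehmann
pseudomedians with signed-rank confidence intervals.

See `docs/methods.md` for the algorithms, numerical choices, and a frank
discussion of what the phantom study can and cannot show.

## Worked example

Fit one noiseless decay curve with both methods:

```python
import numpy as np
from t2biexp import BiexpParams, EchoSeries, biexp_signal, wscd_fit, gn_fit

te = np.arange(9.0, 73.0, 9.0)                      # TE = 9..72 ms
truth = BiexpParams(a_s=1200, a_l=1800, t_s=15, t_l=60)
series = EchoSeries(te, biexp_signal(truth, te))    # noiseless decay curve

wscd = wscd_fit(series, rng_seed=1)
gn = gn_fit(series)
```

prints (via the f-strings in the example script):

```text
wscd: T_S=15.000  T_L=60.000  A_S=1200.0  A_L=1800.0  objective=3.92e-13
gn  : T_S=15.000  T_L=60.000  A_S=1200.0  A_L=1800.0  objective=6.46e-26
```

Both fitters recover the ground truth exactly; the objective is the
(weighted) sum of squared residuals over the eight echoes, at machine
precision here.

On noisy data single-voxel estimates scatter widely — that is the physics
of the problem, not a bug — so the interesting quantity is the accuracy
over many voxels. One cell of the phantom study:

```python
from t2biexp.simulation_study import run_study_cell
cell = run_study_cell(sigma=150.0, method="gn", n_voxels=1000, seed=1)
print(cell.table.round(3).to_string(index=False))
```

```text
component  snr method   n  mean_diff     sd  pseudomedian  ci_low  ci_high     p
      T_S 20.0     gn 997      9.142 18.879         7.998   6.855    9.173 0.000
      T_L 20.0     gn 707     12.674 71.841        -2.115  -3.618   -0.455 0.014
```

Reading: at SNR 20 the Gauss–Newton reference overestimates the short
component by ~9 ms on average and the long component by ~13 ms; `n` counts
the voxels whose fit actually extracted that component (times driven to
the clamp box and constant-class voxels are excluded).

## Command line

```sh
t2biexp simulate --sigma 50 --seed 1 --out phantom/
t2biexp fit --method wscd --radius 2 --seed 1 phantom/phantom.nii.gz maps/
t2biexp evaluate --truth phantom/ --fits maps/ --out table.csv
```

Multi-echo stacks are NIfTI-1 volumes (rows × cols × echoes) with a JSON
sidecar listing the echo times; `fit` writes one NIfTI map per parameter,
an outcome-class map, and a provenance record (config + seed + version).

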