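# Methods

`t2biexp` reconstructs voxelwise biexponential T2 maps from multi-echo
magnitude MRI. This note records the models, the numerical choices, and the
limits of what the synthetic tests demonstrate.

## Signal model

The transverse-relaxation signal of a two-compartment voxel at echo time
`t` (ms) is

    f(t) = A_S exp(-t/T_S) + A_L exp(-t/T_L) + n

with short/long amplitudes `A_S, A_L >= 0` (signal units), relaxation times
`0.1 <= T_S <= T_L <= 5000` ms, and a constant offset `n` absorbing the mean
noise level. The per-voxel objective minimised by the weighted stochastic
fitter applies per-echo weights `W(t)` to the exponential terms only:

    g(theta) = sum_t [ W(t) A_S e^(-t/T_S) + W(t) A_L e^(-t/T_L) + n - y(t) ]^2

The Gauss-Newton reference fits the four-parameter model (no offset) to the
raw signal, `W == 1`.

Every fit is classified into one of three outcomes: *biexponential* (two
components with amplitude above 1% of the voxel maximum, times below the
1000 ms "infinity" threshold, and `T_L/T_S >= 1.05`), *monoexponential*
(exactly one effective component, or indistinct times), or *constant*
(no effective component). The thresholds are deterministic realisations of
the qualitative three-outcome taxonomy; they matter mainly at low SNR,
where they decide which voxels enter the accuracy statistics.

## Neighbourhood weights

For each voxel P and echo t the weights compare P with every neighbour Q in
a `(2r+1) x (2r+1)` window (default `r = 2`, user-configurable; windows are
clipped at image borders, no padding):

    alpha(P,Q,t) = exp(-||P-Q||^2 / sigma^2) exp(-(y_P(t)-y_Q(t))^2 / sigma^2)
    omega(P,Q,t) = y_Q(t) / y_P(t)
    W_P(t)       = n_TE * sum_Q alpha*omega / sum_t sum_Q alpha

`sigma^2` is the per-voxel, per-echo sample variance of the window
(population divisor, floored at 1e-6), used in both exponents. `omega` is
guarded to 1 where `y_P <= 0` (air background). On a spatially constant
image W collapses to exactly 1, and with `omega == 1` substituted the
weights of each voxel average to exactly 1 over echoes; both identities are
tested.

**Known limitation.** On the synthetic phantom this construction produces
weights with a per-echo standard deviation near 0.3 at sigma = 50, because
the intensity-difference exponent `(y_P-y_Q)^2 / sigma^2` is an O(1) random
quantity when the local variance is itself the noise variance. Multiplying
the model by such weights acts as ~30% multiplicative noise and biases the
long component low by tens of ms (see the accuracy discussion below). We
evaluated several re-interpretations (reciprocal intensity ratio, global
noise bandwidth, bandwidth multiples, weighting the data instead of the
model); none removes the effect while preserving the defining identities
above, so the printed construction is kept.

## The weighted stochastic conjugate-direction fitter

Derivative-free minimisation of `g` over `(T_S, T_L, A_S, A_L, n)`:

* **Initialisation.** Ordinary least squares of `ln y` on `t` over the
  positive echoes gives a monoexponential `(T, A)`; the start point is
  `(0.75T, 1.25T, A/2, A/2, 0)`. If fewer than two echoes are positive or
  the decay rate is non-positive, `T` falls back to the echo-time
  mid-range and `A` to the maximum intensity.
* **Normalised search space.** The optimiser works in coordinates where
  times are in ms and amplitudes/offset are in hundredths of the voxel's
  maximum intensity. A single initial step length (default 10) is
  meaningful on every axis only after this normalisation; in raw units no
  conjugate-direction variant we tested could traverse the amplitude
  valley.
* **Segmented bidirectional line search.** Each search direction `v` is
  probed at 21 equidistant points on `[x - v, x + v]`; while the best probe
  sits at a segment end the segment doubles (bracket expansion). Probe
  maxima split the final segment into unimodal pieces; the interior
  minimum of each piece is refined by Brent's method (relative tolerance
  1e-6, 100 iterations); both endpoints always remain candidates.
  Non-finite probes count as +inf.
* **Conjugate-direction cycle.** The five directions are minimised
  sequentially; the net displacement replaces the direction of largest
  single decrease, guarded by the classic extrapolation acceptance test so
  the direction set cannot degenerate.
* **Stochastic candidate list.** Alternative local minima met during line
  searches are pushed onto a list of states (capacity 64, worst evicted)
  together with the direction set. Each iteration re-expands the best
  state plus up to nine uniformly chosen others; successors are kept while
  they improve at all, and a state whose cycle stalls is dropped. The run
  stops when the best point moves less than 1e-4 (normalised units)
  between iterations, the list empties, or 200 iterations elapse. The best
  objective value is non-increasing by construction (tested).
* **Determinism.** A splitmix64 counter drives the stochastic selection;
  whole-image runs derive per-voxel streams as `seed XOR flat_index`, so a
  sub-mask reproduces a full run bit-exactly.

The per-voxel kernel is compiled with numba; a fit takes single-digit
milliseconds. Generic (callable-agnostic) `segmented_line_search` and
`powell_cycle` reference implementations are exposed for testing and
experimentation.

On noiseless phantoms the fitter recovers all five parameters to machine
precision for most of the 25 (T_S, T_L) combinations; the hardest cells
(T_S >= 20 ms, component time ratio below ~3) stall in the flat valley of
the 5-parameter problem with relative errors up to ~15%. The median
relative error across the grid is < 2% and is asserted in the acceptance
suite.

## Gauss-Newton reference

Projected, damped Gauss-Newton on the 4-parameter model: analytic
Jacobian, Levenberg damping multiplied by 10 until a step decreases the
sum of squares (this also covers singular normal equations) and by 0.3
after each accepted step, iterates clipped to the box after every step,
stop at relative decrease < 1e-10 or 200 iterations. It matches a trusted
bounded trust-region least-squares solver to ~1e-4 relative on clean data
and to ~0.01 ms in phantom-level accuracy summaries. A plain step-halving
variant (no damping on accepted steps) was measurably worse — T_S bias
+6.9 ms instead of +2.6 ms at sigma = 50 — and was replaced.

## Synthetic phantom

A 100 x 100 image tiled into 25 subimages of 20 x 20 pixels; each subimage
carries one (T_S, T_L) pair from {5,10,15,20,25} x {40,50,60,70,80} ms in
row-major order, at fixed amplitudes A_S = 1200, A_L = 1800, sampled at
TE = 9, 18, ..., 72 ms. Noise of SD sigma in {50, 75, 150, 300, 600} gives
phantom-level SNR = (A_S+A_L)/sigma in {60, 40, 20, 10, 5}. Gaussian noise
is added when SNR >= 7 (negatives kept, as magnitude subtraction is not
modelled); below that the Rician magnitude `sqrt((s+g1)^2 + g2^2)` is used.
The generator is seeded and bit-reproducible.

What the phantom does not emulate: spatial signal gradients within tiles,
coil-sensitivity variation, stimulated echoes, partial volume at tile
borders beyond a hard edge, or spatially varying noise. Passing tests on
the phantom therefore demonstrate correctness of the pipeline and its
behaviour under idealised piecewise-constant anatomy, not clinical-image
performance.

## Accuracy statistics

Per component (T_S, T_L), the per-voxel differences (estimated - true) are
summarised by mean, sample SD (n-1), the two-sided Wilcoxon signed-rank
test against zero (exact enumeration for tie-free n <= 25, else normal
approximation with continuity correction), and the Hodges-Lehmann
pseudomedian with its 95% signed-rank confidence interval (Walsh-average
order statistics; exact critical ranks by dynamic programming for n <= 25).

A voxel contributes a component's difference only when the fit extracted
that component: constant-class voxels are excluded, as are components with
amplitude below the floor or time above the 1000 ms threshold (a time
driven to the clamp box is "close to infinity", not an estimate). Without
this rule the long-component mean difference is dominated by clamp
saturations (hundreds of ms with SDs near 1000). `include_degenerate=True`
disables all filtering.

Goodness of fit is the per-voxel sum of squared residuals at the fitted
parameters (weighted model for the weighted fitter); map quality is the
ratio of mean map value in a signal region to the mean in a background
region.

## What the simulation study shows — and what it cannot

The acceptance study fits 1,000 randomly sampled phantom voxels per (noise
level, method) cell. The Gauss-Newton reference reproduces the published
qualitative pattern — positive short-component bias at high SNR (+2.6 ms
at SNR 60) and a long-component bias at SNR 20 (+12.7 ms) close to the
published value — and its deviations are significant at essentially every
noise level.

The published weighted-method accuracy (mean differences of a few tenths
of a ms with SDs near 3 ms at SNR 60) is not reachable by this — or, we
argue, any — per-voxel estimator under the stated conditions: the
Cramér-Rao bound for the 4-parameter model at sigma = 50 already exceeds
those SDs several-fold (e.g. sd(T_L) >= 34 ms at (15, 60) ms), and the
5-parameter model is worse. Our weighted fits additionally inherit the
long-component bias of the printed weight construction. The corresponding
acceptance checks are kept at their published tolerances and fail
honestly; the package reports what the described procedure actually
produces.

## Reproducibility plumbing

Multi-echo stacks travel as NIfTI-1 volumes with JSON sidecars carrying
echo times (plus sigma/seed for phantoms); parameter maps are one NIfTI
volume each plus an integer outcome-class map; every CLI run writes a
provenance JSON (configuration, seed, package version). Unfitted voxels
are NaN in float maps and -1 in the class map. The acceptance script
derives all randomness from a single `--seed` and completes in about half
a minute on one CPU.
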