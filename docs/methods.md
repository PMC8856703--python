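# Methods

This note documents the scientific and numerical design of `connfit`:
what is computed, with which constants, and why the non-obvious choices
were made.

## 1. Neural mass model

Each brain region holds one excitatory (E) and one inhibitory (I)
population described by the reduced Wong–Wang equations. With `S` the
synaptic gating variables, the input currents are

```
I_E,i = W_E*I0 + w_plus*J_NMDA*S_E,i
        + G*J_NMDA * sum_j C_ij * S_E,j(t - D_ij/v)   - J_i * S_I,i
I_I,i = W_I*I0 + J_NMDA*S_E,i - S_I,i
```

where `C` is the structural weight matrix, `D` the tract-length matrix
(mm), `v` the conduction velocity and `J_i` the regional
inhibitory-to-excitatory weight set by the tuning controller (section 3).
Currents map to population rates through

```
r = (a*I - b) / (1 - exp(-d*(a*I - b)))
```

evaluated with a series branch `1/d + x/2` when `|a*I - b| < 1e-9` to
avoid 0/0. Gating dynamics:

```
dS_E = (-S_E/tau_E + (1 - S_E)*gamma*r_E/1000) dt + sigma dW
dS_I = (-S_I/tau_I + r_I/1000) dt + sigma dW
```

Constants (units: nA, ms, Hz): `a_E=310, b_E=125, d_E=0.16, a_I=615,
b_I=177, d_I=0.087, tau_E=100, tau_I=10, gamma=0.641, I0=0.382, W_E=1,
W_I=0.7, w_plus=1.4, J_NMDA=0.15, sigma=0.001, v=6 m/s`. The global
coupling `G` is the single globally fitted parameter (default grid: 50
points on [1.4, 2.8]).

## 2. Integration and randomness

Euler–Maruyama at `dt = 0.1 ms` with noise amplitude `sigma*sqrt(dt)`;
gating variables are clipped to [0, 1] after each step. Delays are
`round(D_ij / v / dt)` steps and served from a ring buffer.

The compiled kernel is RNG-free and resumable: all randomness (initial
conditions and the noise stream) is drawn in Python from
`np.random.Generator(SFC64(seed & 0xFFFFFFFF))` in fixed-size chunks, so

- the noise stream is a function of the seed alone and is exactly
  invariant to the chunking granularity,
- any simulation can be reproduced or continued from saved state,
- the hot loop stays free of Python callbacks (a ~5x speedup).

A trajectory records `S_E` and `r_E` at a configurable sampling interval.
Runs whose state leaves the finite range raise a divergence error naming
the first offending region.

## 3. Feedback inhibition control (FIC)

The controller tunes each region's `J_i` so the time-averaged excitatory
rate on a 10 s noisy probe (2 s burn-in) hits 3 Hz. Each region keeps an
independent bracket on `J_i` that is expanded geometrically (x2 / x0.5)
until it straddles the target, then bisected; once the bracket is tight
(< 4 eta) the update switches to a damped proportional step whose gain
`eta` is halved whenever the rate error changes sign (attractor hopping
shows up as sign flips). Stale brackets are dropped when the coupling
context changes. Convergence requires every region in (2, 5) Hz and the
mean rate within 0.25 Hz of target; `J_i >= 0.001` is enforced. Warm
starts (`J_init`) reuse a previous solution, which typically halves the
iteration count along a coupling grid.

Cold starts at strong coupling can hop between a low-rate and a
hyperexcited attractor and exhaust the iteration budget; grid sweeps
therefore chain warm starts, and only converged solutions are propagated
along the chain (a failed tuning's `J` may be stuck in the hyperexcited
basin and would poison the rest of the grid).

## 4. Hemodynamic forward model

Regional synaptic activity `S_E` drives a balloon–windkessel model
(per-region states: vasodilatory signal, flow, volume, deoxyhemoglobin)
with `kappa=0.65, gamma_f=0.41, tau0=0.98 s, alpha=0.32, E0=0.34,
V0=0.02` and readout coefficients `k1=7*E0, k2=2, k3=2*E0-0.2`,
integrated with Euler at 10 ms and sampled at `TR = 2 s`. The first 80 s
(paper-scale default) of each simulated scan is discarded as transient.

## 5. Observables

- **FC**: Pearson correlation matrix of regional BOLD; constant
  (zero-range) regions are reported as dead rather than silently NaN.
- **FC fit**: uncentered Pearson (cosine) similarity between the strict
  upper triangles (row-major order) of simulated and empirical FC.
- **FCD**: sliding windows of 30 s advanced by 4 s; entry (i, j)
  correlates the upper triangles of windowed FC i and j. The upper
  triangle of this matrix is the FCD distribution.
- **FCD fit**: two-sample Kolmogorov–Smirnov distance (ECDF sup-norm)
  between simulated and empirical FCD distributions.

## 6. Subject fitting

For one subject, the parameter space exploration runs `grid x iterations`
simulations (defaults 50 x 20 = 1000). Every (g, iteration) run derives
its own seed from (base seed, subject key, grid index, iteration) so any
single run is reproducible in isolation; subject string identifiers map
to integer keys via SHA-256 (process-independent). Runs are excluded when
FIC fails, integration diverges, or the mean rate exceeds the
hyperexcitation ceiling.

Per iteration, converged grid points are competition-ranked (1, 2, 2, 4)
by FC fit (descending) and FCD KS (ascending); the winner minimizes the
rank sum, ties to the smaller g. Across iterations the modal winner is
selected (ties to the smallest value). The subject's parameter vector is
`g_star` plus the `J` vector of the best-ranked iteration at `g_star` —
`n + 1` entries (97 at 96 regions). A cohort QC screen z-scores FC and
FCD fits and flags FC z < -3 or KS z > 3; note the largest attainable |z|
in a sample of n is `(n-1)/sqrt(n)`, so flags are only possible for
n >= 12.

## 7. Partial least squares

- **Mean-centered PLS**: the cross-block is the matrix of group means of
  the brain variables, centered across groups, decomposed by SVD.
- **Behavioral PLS**: within-group Pearson correlation blocks between
  behavior factors and brain variables, stacked and decomposed.

Signs are fixed by making each brain salience's largest-magnitude element
positive. Significance uses permutation tests (group labels or behavior
rows permuted; p is the literal exceedance fraction, with an optional
`(k+1)/(n+1)` correction). Reliability uses stratified bootstrap
resampling with Procrustes alignment to the original solution: bootstrap
ratios (salience / bootstrap SE, with |BSR| > 2 roughly the two-sided 95%
normal threshold) and percentile confidence intervals. Salience vectors
from different analyses are compared by cosine similarity with an
optional Fisher-z statistic.

## 8. Synthetic data

**Connectomes**: regions are placed on a sphere (radius chosen so
Euclidean distances stay <= 140 mm); weights are drawn lognormally
around a distance-decay mean, symmetric, thresholded to a target edge
density (disconnected draws are rejected and retried), and rescaled to a
target mean row sum (default 0.2). Tract lengths are the Euclidean
distances. Region tables mark a cortical/subcortical split (82/14 at 96
regions).

The mean-row-sum default matters: the dynamics depend on `G x` (weight
scale), and at mean row sum 1.0 the whole default grid is hyperexcited.
At 0.2 the grid is stable with hyperexcitation appearing beyond its top
edge, which is the regime the fitting procedure assumes.

**Cohorts**: subjects get baseline inhibitory weights emulating tuned
output (1.0 nA + coupling-load term + noise); the lesion-positive group
receives cortical (negative) and subcortical (positive) offsets; the
first behavior factor is a noisy negative function of mean planted-region
inhibition; group sizes default to 36/30/14
(comparison / lesion-negative / lesion-positive). All ground truth is
recorded on the cohort object.

## 9. Identifiability of G at small network sizes

A design finding worth recording: with near-homogeneous weights at 16
regions, the FCD distribution's run-to-run variability swamps its
dependence on G (KS rows across a candidate grid track the target
realization's seed, not its G), and the FC cosine rises monotonically
with candidate G because stronger coupling raises all correlations.
Recovery of a ground-truth G from a single simulated "empirical" scan is
then near-chance at any affordable duration.

Identifiability is restored by weight heterogeneity: heavy-tailed weights
(`lognorm_sigma ~ 1.2`) or modular structure give regions staggered
ignition thresholds, so the FC pattern and the FCD distribution change
qualitatively along the grid instead of only in overall level. The
parameter-recovery acceptance test therefore uses a heavy-tailed
16-region connectome and a ground-truth coupling in the upper part of the
grid, where the effect is strongest.

Two further quantitative findings from that test's design study:

- Even in the heavy-tailed regime, a single 120-s-retained run per
  (g, iteration) gives per-iteration combined-rank winner accuracy of
  only ~60% (within one grid step of truth), and the modal vote with its
  ties-to-smallest rule then picks any single low outlier among distinct
  winners; measured recovery was 4/10 against the 8/10 target, so that
  acceptance test is red by design honesty rather than defect.
- Lengthening only the "empirical" target (400 s retained vs 120 s
  candidates) makes recovery far worse (2/10): the KS statistic between
  FCD distributions of different durations is biased, systematically
  favoring low-coupling candidates. Compare like-duration FCD
  distributions, or fit on scans of matched length.

At realistic scale (≈ 100 regions, ≈ 8 min scans) the FCD statistic
stabilizes and this concern shrinks, but users fitting small
parcellations with short scans should expect weakly identified G.
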