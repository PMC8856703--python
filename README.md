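# connfit

Personalized connectome-based dynamic mean field modelling: simulate
whole-brain resting-state BOLD from a structural connectome, fit a
per-subject global coupling parameter and regional inhibitory weights to
static and dynamic functional connectivity, and relate the fitted
parameters to group membership and behavior with multivariate partial
least squares (PLS) — all exercisable end-to-end on synthetic cohorts.

## What it does

1. **Simulate**: each brain region is a reduced Wong–Wang
   excitatory/inhibitory neural mass; regions are coupled through the
   structural connectome with conduction delays and integrated with
   Euler–Maruyama at 0.1 ms. Synaptic activity is passed through a
   balloon–windkessel hemodynamic model to produce BOLD at TR = 2 s.
2. **Tune**: feedback inhibition control (FIC) adjusts each region's
   inhibitory weight `J_i` until its excitatory population fires at
   ~3 Hz, keeping the network in a physiological regime at any coupling.
3. **Fit**: a grid search over the global coupling `G` (with repeated
   stochastic iterations) scores each run by FC similarity (uncentered
   Pearson of upper triangles) and FCD similarity (Kolmogorov–Smirnov
   distance between sliding-window FCD distributions), combines the two
   by rank, and selects the modal winner across iterations. The subject
   is summarized by `G*` plus the tuned `J` vector (`n_regions + 1`
   parameters).
4. **Analyze**: mean-centered and behavioral PLS with permutation tests,
   stratified bootstrap ratios, and percentile confidence intervals
   relate the fitted parameters to groups and behavior factors.
5. **Generate**: a synthetic-data module produces distance-dependent
   lognormal connectomes and cohorts with planted group and
   brain–behavior effects, with full ground truth recorded, so the whole
   pipeline is testable without any empirical data.

See [docs/methods.md](docs/methods.md) for equations, constants, and the
rationale behind the numerical design.

## Worked example

Simulate a tuned 16-region network and compute its observables:

```python
from connfit.synthetic import generate_connectome
from connfit.params import DMFParams
from connfit.fic import tune_fic, measure_rates
from connfit.simulate import simulate
from connfit.bold import bold_from_activity, remove_transient
from connfit.observables import fc_matrix, fcd_matrix, upper_triangle

conn = generate_connectome(16, density=0.3, seed=42)
params = DMFParams(G=1.6)
fic = tune_fic(conn, params, seed=1)
print(f"FIC converged: {fic.converged} after {len(fic.history)} iterations")

traj = simulate(conn, params, fic.J, duration=120_000.0, seed=2)
rates = measure_rates(traj, burn_in=20_000.0)
print(f"mean excitatory rate: {rates.mean():.2f} Hz "
      f"(range {rates.min():.2f}-{rates.max():.2f} Hz)")

bold = remove_transient(bold_from_activity(traj, tr=2.0), 20.0)
print(f"BOLD: {bold.n_regions} regions x {bold.n_volumes} volumes at TR {bold.tr:.0f} s")
fc = fc_matrix(bold)
fcd = fcd_matrix(bold, 30.0, 4.0)
print(f"mean FC (upper triangle): {upper_triangle(fc).mean():.3f}")
print(f"FCD: {fcd.values.shape[0]} x {fcd.values.shape[0]} windows")
```

Output:

```
FIC converged: True after 7 iterations
mean excitatory rate: 2.81 Hz (range 2.49-3.39 Hz)
BOLD: 16 regions x 50 volumes at TR 2 s
mean FC (upper triangle): 0.103
FCD: 18 x 18 windows
```

Group analysis on a synthetic cohort with a planted lesion effect:

```python
import numpy as np
from connfit.synthetic import generate_cohort
from connfit.pls import mean_centering_pls

cohort = generate_cohort(seed=7, shared_connectome=True)
print(f"{cohort.n_subjects} subjects")
res = mean_centering_pls(cohort.brain_matrix(), cohort.group,
                         n_perm=500, n_boot=500, random_state=0)
print(f"LV1: {res.covariance_explained[0] * 100:.1f}% covariance, "
      f"perm p = {res.perm_p[0]:.4f}")
print(f"regions with |BSR| > 2 on LV1: "
      f"{int(np.sum(np.abs(res.bootstrap_ratios[:, 0]) > 2))}")
```

Output:

```
80 subjects
LV1: 99.8% covariance, perm p = 0.0000
regions with |BSR| > 2 on LV1: 16
```

## Command line

```bash
connfit make-synthetic --regions 16 --per-group 3,3,3 --seed 1 --out cohort/
connfit simulate --connectome conn.zip --g 1.6 --duration 120 --cut 20 \
    --seed 2 --out bold.tsv
connfit fit-subject --connectome conn.zip --bold bold.tsv \
    --grid-n 5 --iterations 2 --seed 3 --subject-id sub-001 --out fits/
connfit pls meancenter --brain brain.tsv --nperm 500 --nboot 500 \
    --seed 4 --out pls/
connfit run-all --config config.yaml
```

Every output directory carries a JSON manifest with the configuration
hash and all seeds needed to regenerate it; subject identifiers map to
seeds via a process-independent hash, so reruns are bit-reproducible.

## Scale presets

- `fast`: 16 regions, 5-point grid, 2 iterations — minutes, for CI and
  exploration.
- `paper`: 96 regions, 50-point grid, 20 iterations (1000 simulations
  per subject), 1000 permutations/bootstraps — a realistic study layout.

## A note on fitting small networks

At small region counts and short scan durations, the global coupling is
weakly identified when connectome weights are near-homogeneous: the FCD
distribution is dominated by realization noise and FC similarity rises
monotonically with coupling. Heterogeneous (heavy-tailed or modular)
weights make the fit well-posed. See the closing section of
[docs/methods.md](docs/methods.md) before fitting parcellations much
below ~100 regions.

## Layout

- `src/connfit/` — package (`simulate`, `fic`, `bold`, `observables`,
  `fitting`, `pls`, `synthetic`, `connectome`, `pipeline`, `cli`, `io`,
  `params`)
- `tests/` — unit, property-based, and acceptance suites
- `scripts/acceptance.py` — recomputes the firing-rate acceptance
  targets from scratch: `python scripts/acceptance.py --seed 1 --out targets.json`
- `docs/methods.md` — model equations, constants, and design rationale
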