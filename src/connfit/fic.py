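"""Feedback inhibition control: tune regional inhibitory weights J_i.

Long-range excitation grows with global coupling, so without compensation
strongly connected regions fire unrealistically fast. The controller probes
the model with short stochastic epochs and adjusts each region's inhibitory
weight until every excitatory population's time-averaged rate sits in the
physiological band around the ~3 Hz target. The steady-state rate is a
monotone decreasing function of J_i, so each region is handled as a
one-dimensional root find: expand geometrically until the target rate is
bracketed, bisect the bracket, then switch to a damped proportional update
J_i <- J_i + eta_i * (rate_i - target) once the bracket is tight; eta_i is
halved whenever the region's error changes sign, and J_i is floored at a
small positive minimum. Probes are stochastic, so a bracket bound
contradicted by a later measurement is discarded rather than trusted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectome import Connectome
from .params import DMFParams
from .simulate import NeuralTrajectory, simulate

__all__ = ["FICResult", "tune_fic", "measure_rates"]

DEFAULT_TARGET_RATE = 3.0  # Hz
DEFAULT_BAND = (2.0, 5.0)  # Hz
DEFAULT_PROBE_DURATION = 10_000.0  # ms of simulated probe epoch
DEFAULT_BURN_IN = 2_000.0  # ms discarded at the start of each probe
DEFAULT_MAX_ITERATIONS = 12
DEFAULT_ETA = 0.15  # nA per Hz of rate error
J_FLOOR = 0.001  # nA
MEAN_RATE_TOL = 0.25  # Hz: |cohort-mean rate - target| required for convergence


def measure_rates(
    trajectory: NeuralTrajectory, burn_in: float = DEFAULT_BURN_IN
) -> np.ndarray:
    """Time-averaged excitatory firing rate per region, Hz.

    Averages the recorded rate series over the window after ``burn_in`` ms.
    """
    if trajectory.duration <= burn_in:
        raise ValueError(
            f"epoch of {trajectory.duration} ms is not longer than the "
            f"{burn_in} ms burn-in"
        )
    start = int(np.ceil(burn_in / trajectory.sample_interval))
    return trajectory.r_E[:, start:].mean(axis=1)


@dataclass
class FICResult:
    """Outcome of inhibitory-weight tuning."""

    J: np.ndarray
    region_rates: np.ndarray
    converged: bool
    iterations_used: int
    history: list = field(default_factory=list)  # per-iteration max |rate - target|

    def __post_init__(self) -> None:
        if self.converged:
            assert self.region_rates.size == self.J.size


def tune_fic(
    connectome: Connectome,
    params: DMFParams,
    target_rate: float = DEFAULT_TARGET_RATE,
    band: tuple[float, float] = DEFAULT_BAND,
    seed: int = 0,
    max_iterations: int = DEFAULT_MAX_ITERATIONS,
    *,
    J_init: np.ndarray | None = None,
    probe_duration: float = DEFAULT_PROBE_DURATION,
    burn_in: float = DEFAULT_BURN_IN,
    eta: float = DEFAULT_ETA,
    sample_interval: float = 10.0,
    mean_rate_tol: float = MEAN_RATE_TOL,
) -> FICResult:
    """Tune J so every region's mean excitatory rate lies in ``band``.

    Convergence requires every region inside the band and the cross-region
    mean rate within ``mean_rate_tol`` of ``target_rate``. A failed tuning
    returns ``converged=False`` with the error history as diagnostics; it is
    never silently ignored. ``J_init`` warm-starts from a previously tuned
    vector (all regions start at 1.0 nA otherwise).
    """
    low, high = band
    if not low <= target_rate <= high:
        raise ValueError(f"target {target_rate} Hz outside band {band}")
    n = connectome.n_regions
    J = np.ones(n) if J_init is None else np.asarray(J_init, dtype=float).copy()
    # bracket of the monotone rate-vs-J curve per region:
    # rate > target at J_lo (inhibition too weak), rate < target at J_hi
    J_lo = np.full(n, np.nan)
    J_hi = np.full(n, np.nan)
    eta_vec = np.full(n, eta)
    prev_err = np.zeros(n)
    history: list[float] = []
    rates = np.full(n, np.nan)
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0xF1C])
    probe_seeds = ss.generate_state(max_iterations) % (2**31 - 1)
    for it in range(max_iterations):
        traj = simulate(
            connectome,
            params,
            J,
            duration=probe_duration,
            seed=int(probe_seeds[it]),
            sample_interval=sample_interval,
        )
        rates = measure_rates(traj, burn_in=burn_in)
        err = rates - target_rate
        history.append(float(np.max(np.abs(err))))
        in_band = (rates >= low) & (rates <= high)
        if np.all(in_band) and abs(rates.mean() - target_rate) <= mean_rate_tol:
            return FICResult(
                J=J, region_rates=rates, converged=True,
                iterations_used=it + 1, history=history,
            )
        too_fast = err > 0  # rate above target -> raise J
        J_lo[too_fast] = J[too_fast]
        J_hi[~too_fast] = J[~too_fast]
        # a noisy probe can invert a bracket; drop the stale bound
        stale = J_lo >= J_hi
        J_hi[stale & too_fast] = np.nan
        J_lo[stale & ~too_fast] = np.nan
        bracketed = np.isfinite(J_lo) & np.isfinite(J_hi)
        with np.errstate(invalid="ignore"):
            proposal = np.where(
                bracketed,
                0.5 * (J_lo + J_hi),
                np.where(too_fast, 2.0 * J, 0.5 * J),
            )
        # proportional refinement once the bracket is tight; halve the
        # per-region step whenever the error changes sign so the loop gain
        # drops below one and the oscillation damps out
        flipped = err * prev_err < 0
        eta_vec[flipped] *= 0.5
        prev_err = err
        tight = bracketed & (J_hi - J_lo < 4 * eta)
        proposal[tight] = J[tight] + eta_vec[tight] * np.clip(err[tight], -2.0, 2.0)
        J = np.maximum(proposal, J_FLOOR)
    return FICResult(
        J=J, region_rates=rates, converged=False,
        iterations_used=max_iterations, history=history,
    )
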