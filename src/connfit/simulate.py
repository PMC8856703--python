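"""Stochastic delayed integration of the reduced Wong-Wang mean field model.

Each region i carries an excitatory and an inhibitory population described by
synaptic gating variables S_i^(E), S_i^(I) in [0, 1]. Input currents are

    I_i^(E) = W_E*I0 + w+*J_NMDA*S_i^(E)
              + G*J_NMDA * sum_j C_ij * S_j^(E)(t - D_ij/velocity)
              - J_i * S_i^(I)
    I_i^(I) = W_I*I0 + J_NMDA*S_i^(E) - S_i^(I)

currents map to population firing rates through the sigmoidal-linear
transfer function r = (a*I - b) / (1 - exp(-d*(a*I - b))), and the gating
variables evolve by Euler-Maruyama with independent standard-normal noise
per region and population:

    dS^(E) = dt*(-S^(E)/tau_E + (1 - S^(E))*gamma*r^(E)/1000) + sigma*sqrt(dt)*v
    dS^(I) = dt*(-S^(I)/tau_I + r^(I)/1000) + sigma*sqrt(dt)*v'

(times in ms, rates in Hz, hence the explicit Hz -> 1/ms factor). Long-range
coupling is delayed by the tract length over the conduction velocity, rounded
to the nearest integer step; gating is clipped to [0, 1] after each step.

The production integrator is a numba kernel; ``simulate_reference`` is a
plain-numpy twin that consumes the identical random stream, used as an
independent cross-check at small problem sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .connectome import Connectome
from .params import DMFParams

__all__ = [
    "IntegrationDivergedError",
    "NeuralTrajectory",
    "transfer_rate",
    "excitatory_input",
    "inhibitory_input",
    "delay_steps",
    "simulate",
    "simulate_reference",
]

_SERIES_EPS = 1e-9  # |a*I - b| below this switches to the series expansion


class IntegrationDivergedError(RuntimeError):
    """Raised when the neural or hemodynamic state becomes non-finite."""

    def __init__(self, step: int, message: str | None = None):
        self.step = step
        super().__init__(message or f"integration diverged at step {step}")


def transfer_rate(current, a: float, b: float, d: float):
    """Population transfer function: current (nA) to firing rate (Hz).

    r = x / (1 - exp(-d*x)) with x = a*current - b, continuous at x = 0
    where the limit is 1/d.
    """
    if d <= 0:
        raise ValueError("d must be positive")
    x = a * np.asarray(current, dtype=float) - b
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    out = np.empty_like(x)
    small = np.abs(x) < _SERIES_EPS
    xs = x[~small]
    out[~small] = xs / (1.0 - np.exp(-d * xs))
    # first-order expansion of x/(1 - e^{-dx}) about x = 0
    out[small] = 1.0 / d + x[small] / 2.0
    return float(out[0]) if scalar else out


def excitatory_input(
    S_E: np.ndarray,
    S_I: np.ndarray,
    params: DMFParams,
    J: np.ndarray,
    C: np.ndarray,
    S_E_delayed: np.ndarray,
) -> np.ndarray:
    """Excitatory input current per region, nA.

    ``S_E_delayed[i, j]`` must hold S_j^(E)(t - D_ij/velocity).
    """
    coupling = np.sum(C * S_E_delayed, axis=1)
    return (
        params.W_E * params.I0
        + params.w_plus * params.J_NMDA * np.asarray(S_E)
        + params.G * params.J_NMDA * coupling
        - np.asarray(J) * np.asarray(S_I)
    )


def inhibitory_input(S_E: np.ndarray, S_I: np.ndarray, params: DMFParams) -> np.ndarray:
    """Inhibitory input current per region, nA."""
    return params.W_I * params.I0 + params.J_NMDA * np.asarray(S_E) - np.asarray(S_I)


def delay_steps(lengths_mm: np.ndarray, velocity_m_s: float, dt_ms: float) -> np.ndarray:
    """Integer-step conduction delays: round(D_ij / velocity / dt).

    mm divided by m/s gives milliseconds directly.
    """
    lag_ms = np.asarray(lengths_mm, dtype=float) / velocity_m_s
    return np.rint(lag_ms / dt_ms).astype(np.int64)


@dataclass
class NeuralTrajectory:
    """Decimated record of a simulation.

    S_E, r_E : (n, T) excitatory gating and firing rate (Hz) sampled every
        ``sample_interval`` ms (first sample at t = sample_interval).
    """

    S_E: np.ndarray
    r_E: np.ndarray
    sample_interval: float
    seed: int

    @property
    def n_regions(self) -> int:
        return self.S_E.shape[0]

    @property
    def n_samples(self) -> int:
        return self.S_E.shape[1]

    @property
    def duration(self) -> float:
        """Covered duration in ms."""
        return self.n_samples * self.sample_interval


@njit(cache=True)
def _rate(x, d):
    if abs(x) < _SERIES_EPS:
        return 1.0 / d + x / 2.0
    return x / (1.0 - np.exp(-d * x))


@njit(cache=True, fastmath=False)
def _dmf_kernel(
    indptr,
    indices,
    weights,
    edge_delay,
    buf_len,
    n,
    t_start,
    block,
    dt,
    G,
    w_plus,
    J_NMDA,
    sigma,
    I0,
    W_E,
    W_I,
    a_E,
    b_E,
    d_E,
    a_I,
    b_I,
    d_I,
    tau_E,
    tau_I,
    gamma,
    J,
    decim,
    S_E,
    S_I,
    hist,
    S_E_rec,
    r_E_rec,
    noise,
    add_noise,
):
    """One block of Euler-Maruyama steps over a sparse adjacency (CSR layout).

    The kernel is resumable: state (``S_E``, ``S_I``), the delay history
    ring buffer (``hist``) and the record arrays persist across calls, so
    the driver integrates long runs chunk by chunk, generating each chunk's
    noise (``noise[s, 0/1, i]`` for step ``t_start + s``) outside the
    compiled loop. Returns the global step index of divergence, or -1.
    """
    sqrt_dt_sigma = sigma * np.sqrt(dt)
    ext_E = W_E * I0
    ext_I = W_I * I0
    r_E = np.empty(n)
    for s in range(block):
        t = t_start + s
        pos = t % buf_len
        for j in range(n):
            hist[pos, j] = S_E[j]
        for i in range(n):
            coupling = 0.0
            for e in range(indptr[i], indptr[i + 1]):
                k = pos - edge_delay[e]
                if k < 0:
                    k += buf_len
                coupling += weights[e] * hist[k, indices[e]]
            I_E = ext_E + w_plus * J_NMDA * S_E[i] + G * J_NMDA * coupling - J[i] * S_I[i]
            I_I = ext_I + J_NMDA * S_E[i] - S_I[i]
            r_E[i] = _rate(a_E * I_E - b_E, d_E)
            r_I = _rate(a_I * I_I - b_I, d_I)
            S_E[i] += dt * (-S_E[i] / tau_E + (1.0 - S_E[i]) * gamma * r_E[i] / 1000.0)
            S_I[i] += dt * (-S_I[i] / tau_I + r_I / 1000.0)
        if add_noise:
            for i in range(n):
                S_E[i] += sqrt_dt_sigma * noise[s, 0, i]
                S_I[i] += sqrt_dt_sigma * noise[s, 1, i]
        for i in range(n):
            if S_E[i] < 0.0:
                S_E[i] = 0.0
            elif S_E[i] > 1.0:
                S_E[i] = 1.0
            if S_I[i] < 0.0:
                S_I[i] = 0.0
            elif S_I[i] > 1.0:
                S_I[i] = 1.0
        if (t + 1) % decim == 0:
            ok = True
            for i in range(n):
                if not (np.isfinite(S_E[i]) and np.isfinite(S_I[i])):
                    ok = False
            if not ok:
                return t
            rec_idx = (t + 1) // decim - 1
            if rec_idx < S_E_rec.shape[1]:
                for i in range(n):
                    S_E_rec[i, rec_idx] = S_E[i]
                    r_E_rec[i, rec_idx] = r_E[i]
    return -1


def _prepare(connectome: Connectome, params: DMFParams, J, duration, sample_interval):
    J = np.asarray(J, dtype=float)
    n = connectome.n_regions
    if J.shape != (n,):
        raise ValueError(f"J must have shape ({n},), got {J.shape}")
    if np.any(J <= 0):
        raise ValueError("all inhibitory weights J_i must be positive")
    if duration < sample_interval:
        raise ValueError("duration must be at least one sample interval")
    decim = int(round(sample_interval / params.dt))
    if decim < 1 or abs(decim * params.dt - sample_interval) > 1e-9:
        raise ValueError("sample_interval must be a positive multiple of dt")
    n_steps = int(np.floor(duration / params.dt + 1e-9))
    n_rec = n_steps // decim
    dsteps = delay_steps(connectome.lengths, params.velocity, params.dt)
    return J, decim, n_steps, n_rec, dsteps


def simulate(
    connectome: Connectome,
    params: DMFParams,
    J: np.ndarray,
    duration: float,
    seed: int,
    sample_interval: float = 10.0,
    init_state: np.ndarray | None = None,
    noise: np.ndarray | None = None,
) -> NeuralTrajectory:
    """Integrate the coupled model for ``duration`` ms.

    Parameters
    ----------
    J : (n,) positive inhibitory weights per region (nA).
    duration : total simulated time, ms.
    seed : seeds initial conditions (uniform in [0, 0.2]) and the noise
        stream; identical seeds give bitwise-identical trajectories.
    sample_interval : decimation of the recorded series, ms (a multiple of
        params.dt).
    init_state : optional (2, n) explicit initial [S_E; S_I], bypassing the
        random initial draw.
    noise : optional (n_steps, 2, n) pre-generated standard-normal
        increments (row 0 excitatory, row 1 inhibitory), bypassing the
        internal stream. Mainly for cross-checking integrators.
    """
    J, decim, n_steps, n_rec, dsteps = _prepare(
        connectome, params, J, duration, sample_interval
    )
    n = connectome.n_regions
    S_E_rec = np.empty((n, n_rec))
    r_E_rec = np.empty((n, n_rec))
    use_noise = noise is not None
    if use_noise:
        noise_arr = np.ascontiguousarray(noise, dtype=float)
        if noise_arr.shape != (n_steps, 2, n):
            raise ValueError(f"noise must have shape ({n_steps}, 2, {n})")
    rng = np.random.Generator(np.random.SFC64(int(seed) & 0xFFFFFFFF))
    if init_state is not None:
        S_E = np.asarray(init_state[0], dtype=float).copy()
        S_I = np.asarray(init_state[1], dtype=float).copy()
    else:
        S_E = rng.uniform(0.0, 0.2, n)
        S_I = rng.uniform(0.0, 0.2, n)
    add_noise = params.sigma > 0.0 or use_noise
    # CSR-style adjacency: per region the incoming edges with their delays
    C = connectome.weights
    indptr = np.zeros(n + 1, dtype=np.int64)
    cols = []
    for i in range(n):
        nz = np.flatnonzero(C[i])
        cols.append(nz)
        indptr[i + 1] = indptr[i] + nz.size
    indices = (
        np.concatenate(cols).astype(np.int64) if indptr[-1] else np.zeros(0, np.int64)
    )
    edge_w = np.concatenate([C[i, c] for i, c in enumerate(cols)]) if indptr[-1] else np.zeros(0)
    edge_delay = (
        np.concatenate([dsteps[i, c] for i, c in enumerate(cols)]).astype(np.int64)
        if indptr[-1]
        else np.zeros(0, np.int64)
    )
    buf_len = int(edge_delay.max()) + 1 if edge_delay.size else 1
    hist = np.tile(S_E, (buf_len, 1))
    # noise for each chunk is generated here (outside the compiled loop) and
    # consumed step-by-step inside it; one stream, identical regardless of
    # chunk size
    chunk = min(n_steps, max(1024, 3_000_000 // (2 * n)))
    noise_buf = np.empty((chunk, 2, n)) if (add_noise and not use_noise) else np.empty((1, 2, n))
    t0 = 0
    while t0 < n_steps:
        block = min(chunk, n_steps - t0)
        if use_noise:
            chunk_noise = noise_arr[t0 : t0 + block]
        elif add_noise:
            rng.standard_normal(out=noise_buf[:block])
            chunk_noise = noise_buf[:block]
        else:
            chunk_noise = noise_buf
        bad = _dmf_kernel(
            indptr,
            indices,
            edge_w,
            edge_delay,
            buf_len,
            n,
            t0,
            block,
            params.dt,
            params.G,
            params.w_plus,
            params.J_NMDA,
            params.sigma,
            params.I0,
            params.W_E,
            params.W_I,
            params.a_E,
            params.b_E,
            params.d_E,
            params.a_I,
            params.b_I,
            params.d_I,
            params.tau_E,
            params.tau_I,
            params.gamma,
            J,
            decim,
            S_E,
            S_I,
            hist,
            S_E_rec,
            r_E_rec,
            chunk_noise,
            add_noise,
        )
        if bad >= 0:
            raise IntegrationDivergedError(bad)
        t0 += block
    return NeuralTrajectory(
        S_E=S_E_rec, r_E=r_E_rec, sample_interval=sample_interval, seed=int(seed)
    )


def simulate_reference(
    connectome: Connectome,
    params: DMFParams,
    J: np.ndarray,
    duration: float,
    seed: int,
    sample_interval: float = 10.0,
    init_state: np.ndarray | None = None,
    noise: np.ndarray | None = None,
) -> NeuralTrajectory:
    """Plain-numpy integrator consuming the same random stream as ``simulate``.

    Slow; intended as an independent cross-check on short runs.
    """
    J, decim, n_steps, n_rec, dsteps = _prepare(
        connectome, params, J, duration, sample_interval
    )
    n = connectome.n_regions
    rng = np.random.Generator(np.random.SFC64(int(seed) & 0xFFFFFFFF))
    if init_state is not None:
        S_E = np.asarray(init_state[0], dtype=float).copy()
        S_I = np.asarray(init_state[1], dtype=float).copy()
    else:
        S_E = rng.uniform(0.0, 0.2, n)
        S_I = rng.uniform(0.0, 0.2, n)
    max_delay = int(dsteps.max())
    buf_len = max_delay + 1
    hist = np.tile(S_E, (buf_len, 1))
    C = connectome.weights
    dt = params.dt
    S_E_rec = np.empty((n, n_rec))
    r_E_rec = np.empty((n, n_rec))
    rec_idx = 0
    for t in range(n_steps):
        hist[t % buf_len] = S_E
        delayed = hist[(t - dsteps) % buf_len, np.arange(n)[None, :]]
        I_E = excitatory_input(S_E, S_I, params, J, C, delayed)
        I_I = inhibitory_input(S_E, S_I, params)
        r_E = transfer_rate(I_E, params.a_E, params.b_E, params.d_E)
        r_I = transfer_rate(I_I, params.a_I, params.b_I, params.d_I)
        S_E = S_E + dt * (-S_E / params.tau_E + (1 - S_E) * params.gamma * r_E / 1000.0)
        S_I = S_I + dt * (-S_I / params.tau_I + r_I / 1000.0)
        if params.sigma > 0 or noise is not None:
            if noise is not None:
                v_E, v_I = noise[t, 0], noise[t, 1]
            else:
                v = rng.standard_normal((2, n))
                v_E, v_I = v[0], v[1]
            amp = params.sigma * np.sqrt(dt)
            S_E = S_E + amp * v_E
            S_I = S_I + amp * v_I
        S_E = np.clip(S_E, 0.0, 1.0)
        S_I = np.clip(S_I, 0.0, 1.0)
        if (t + 1) % decim == 0:
            if not (np.all(np.isfinite(S_E)) and np.all(np.isfinite(S_I))):
                raise IntegrationDivergedError(t)
            if rec_idx < n_rec:
                S_E_rec[:, rec_idx] = S_E
                r_E_rec[:, rec_idx] = r_E
                rec_idx += 1
    return NeuralTrajectory(
        S_E=S_E_rec, r_E=r_E_rec, sample_interval=sample_interval, seed=int(seed)
    )
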