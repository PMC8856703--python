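"""Integrator correctness: transfer function oracle, fixed points, dual-route
kernel/reference agreement, delays, noise handling and divergence flagging."""

import mpmath
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize

from connfit.params import DMFParams
from connfit.simulate import (
    IntegrationDivergedError,
    delay_steps,
    excitatory_input,
    inhibitory_input,
    simulate,
    simulate_reference,
    transfer_rate,
)

from conftest import ring_connectome


# ---------------------------------------------------------------- transfer

def transfer_oracle(current, a, b, d):
    """Arbitrary-precision r = x/(1 - exp(-d x)) evaluated with mpmath."""
    with mpmath.workdps(50):
        x = mpmath.mpf(a) * mpmath.mpf(current) - mpmath.mpf(b)
        if x == 0:
            return float(1 / mpmath.mpf(d))
        return float(x / (1 - mpmath.e ** (-mpmath.mpf(d) * x)))


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.floats(min_value=-1.0, max_value=2.0))
def test_excitatory_transfer_matches_high_precision_oracle(current):
    got = transfer_rate(current, 310.0, 125.0, 0.16)
    want = transfer_oracle(current, 310.0, 125.0, 0.16)
    assert got == pytest.approx(want, rel=1e-10)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.floats(min_value=-1.0, max_value=2.0))
def test_inhibitory_transfer_matches_high_precision_oracle(current):
    got = transfer_rate(current, 615.0, 177.0, 0.087)
    want = transfer_oracle(current, 615.0, 177.0, 0.087)
    assert got == pytest.approx(want, rel=1e-10)


def test_transfer_is_continuous_through_the_removable_singularity():
    a, b, d = 310.0, 125.0, 0.16
    x0 = b / a  # current where a*I - b = 0
    at = transfer_rate(x0, a, b, d)
    assert at == pytest.approx(1 / d, rel=1e-12)
    eps = 1e-12  # keeps a*I - b within the series branch
    left = transfer_rate(x0 - eps, a, b, d)
    right = transfer_rate(x0 + eps, a, b, d)
    assert left == pytest.approx(at, rel=1e-7)
    assert right == pytest.approx(at, rel=1e-7)


def test_transfer_vectorized_matches_scalar():
    xs = np.linspace(-0.5, 1.5, 11)
    vec = transfer_rate(xs, 310.0, 125.0, 0.16)
    for x, v in zip(xs, vec):
        assert v == transfer_rate(float(x), 310.0, 125.0, 0.16)


def test_transfer_rejects_nonpositive_d():
    with pytest.raises(ValueError):
        transfer_rate(0.5, 310.0, 125.0, 0.0)


# ----------------------------------------------------------- input currents

def test_input_currents_closed_form():
    p = DMFParams(G=2.0)
    S_E = np.array([0.2, 0.4])
    S_I = np.array([0.1, 0.3])
    J = np.array([1.0, 1.5])
    C = np.array([[0.0, 0.5], [0.5, 0.0]])
    delayed = np.tile(S_E, (2, 1))
    I_E = excitatory_input(S_E, S_I, p, J, C, delayed)
    want0 = p.W_E * p.I0 + p.w_plus * p.J_NMDA * 0.2 + p.G * p.J_NMDA * 0.5 * 0.4 - 1.0 * 0.1
    assert I_E[0] == pytest.approx(want0, rel=1e-14)
    I_I = inhibitory_input(S_E, S_I, p)
    assert I_I[1] == pytest.approx(p.W_I * p.I0 + p.J_NMDA * 0.4 - 0.3, rel=1e-14)


# ------------------------------------------------------------------ delays

def test_delay_steps_exact_values():
    lengths = np.array([[0.0, 60.0], [60.0, 0.0]])
    # 60 mm at 6 m/s = 10 ms = 100 steps of 0.1 ms
    assert delay_steps(lengths, 6.0, 0.1)[0, 1] == 100


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    st.floats(min_value=0.1, max_value=300.0),
    st.floats(min_value=1.0, max_value=20.0),
)
def test_delay_steps_round_to_nearest(length, velocity):
    dt = 0.1
    steps = delay_steps(np.array([[length]]), velocity, dt)[0, 0]
    assert abs(steps - length / velocity / dt) <= 0.5 + 1e-9


# ------------------------------------------------------------ fixed points

def uncoupled_fixed_point(params, J=1.0):
    """Root-find the noiseless single-region equilibrium independently."""

    def si_residual(S_I, S_E):
        I_I = params.W_I * params.I0 + params.J_NMDA * S_E - S_I
        r_I = transfer_oracle(I_I, params.a_I, params.b_I, params.d_I)
        return -S_I / params.tau_I + r_I / 1000.0

    def se_residual(S_E):
        S_I = optimize.brentq(
            si_residual, 0.0, 1.0, args=(S_E,), xtol=1e-14
        )
        I_E = params.W_E * params.I0 + params.w_plus * params.J_NMDA * S_E - J * S_I
        r_E = transfer_oracle(I_E, params.a_E, params.b_E, params.d_E)
        return -S_E / params.tau_E + (1 - S_E) * params.gamma * r_E / 1000.0

    S_E = optimize.brentq(se_residual, 0.0, 0.9999, xtol=1e-14)
    S_I = optimize.brentq(si_residual, 0.0, 1.0, args=(S_E,), xtol=1e-14)
    I_E = params.W_E * params.I0 + params.w_plus * params.J_NMDA * S_E - J * S_I
    r_E = transfer_oracle(I_E, params.a_E, params.b_E, params.d_E)
    return S_E, S_I, r_E


def test_noiseless_uncoupled_network_settles_at_the_analytic_equilibrium():
    p = DMFParams(G=0.0, sigma=0.0)
    conn = ring_connectome(4)
    S_E_star, _, r_E_star = uncoupled_fixed_point(p)
    traj = simulate(conn, p, np.ones(4), duration=10_000.0, seed=0)
    assert np.allclose(traj.S_E[:, -1], S_E_star, atol=1e-6)
    assert np.allclose(traj.r_E[:, -1], r_E_star, atol=1e-4)
    # the equilibrium rate of this parameterization is the canonical ~3 Hz
    assert 2.5 < r_E_star < 3.5


# -------------------------------------------- kernel vs reference integrator

def test_kernel_and_reference_consume_identical_streams(small_connectome):
    p = DMFParams(G=1.8)
    J = np.ones(small_connectome.n_regions)
    a = simulate(small_connectome, p, J, duration=2000.0, seed=5)
    b = simulate_reference(small_connectome, p, J, duration=2000.0, seed=5)
    assert np.abs(a.S_E - b.S_E).max() < 1e-10
    assert np.abs(a.r_E - b.r_E).max() < 1e-8


def test_kernel_and_reference_agree_on_supplied_noise(ring6):
    p = DMFParams(G=1.5)
    n_steps = int(1000.0 / p.dt)
    noise = np.random.default_rng(3).standard_normal((n_steps, 2, 6))
    J = np.ones(6)
    a = simulate(ring6, p, J, 1000.0, seed=9, noise=noise)
    b = simulate_reference(ring6, p, J, 1000.0, seed=9, noise=noise)
    assert np.abs(a.S_E - b.S_E).max() < 1e-12


def test_identical_seeds_reproduce_trajectories(ring6):
    p = DMFParams(G=1.5)
    J = np.ones(6)
    a = simulate(ring6, p, J, 1500.0, seed=7)
    b = simulate(ring6, p, J, 1500.0, seed=7)
    assert np.array_equal(a.S_E, b.S_E)
    c = simulate(ring6, p, J, 1500.0, seed=8)
    assert not np.array_equal(a.S_E, c.S_E)


def test_single_step_noise_increment_has_sigma_sqrt_dt_scale(ring6):
    """One Euler step from a fixed state moves by exactly sigma*sqrt(dt)*v."""
    p = DMFParams(G=1.5, sigma=0.01)
    J = np.ones(6)
    init = np.full((2, 6), 0.15)
    noise = np.zeros((1, 2, 6))
    base = simulate(
        ring6, p, J, duration=p.dt, seed=0, sample_interval=p.dt,
        init_state=init, noise=noise,
    )
    kicked_noise = np.zeros((1, 2, 6))
    kicked_noise[0, 0, 2] = 1.0  # unit excitatory kick in region 2
    kicked = simulate(
        ring6, p, J, duration=p.dt, seed=0, sample_interval=p.dt,
        init_state=init, noise=kicked_noise,
    )
    delta = kicked.S_E[:, 0] - base.S_E[:, 0]
    want = p.sigma * np.sqrt(p.dt)
    assert delta[2] == pytest.approx(want, rel=1e-12)
    assert np.all(delta[np.arange(6) != 2] == 0)


def test_gating_is_clipped_to_unit_interval(ring6):
    p = DMFParams(G=1.5, sigma=0.05)  # strong noise to force excursions
    traj = simulate(ring6, p, np.ones(6), 2000.0, seed=11)
    assert traj.S_E.min() >= 0.0
    assert traj.S_E.max() <= 1.0


def test_divergence_is_reported_not_swallowed(ring6):
    p = DMFParams(G=1.5, sigma=0.0)
    init = np.full((2, 6), 0.2)
    n_steps = int(100.0 / p.dt)
    noise = np.zeros((n_steps, 2, 6))
    noise[500, 0, :] = np.nan  # corrupt the stream mid-run
    with pytest.raises(IntegrationDivergedError):
        simulate(ring6, p, np.ones(6), 100.0, seed=0, init_state=init, noise=noise)


# ----------------------------------------------------------------- validation

def test_wrong_J_shape_rejected(ring6):
    with pytest.raises(ValueError, match="shape"):
        simulate(ring6, DMFParams(), np.ones(5), 100.0, seed=0)


def test_nonpositive_J_rejected(ring6):
    J = np.ones(6)
    J[3] = 0.0
    with pytest.raises(ValueError, match="positive"):
        simulate(ring6, DMFParams(), J, 100.0, seed=0)


def test_sample_interval_must_divide_into_dt_multiples(ring6):
    with pytest.raises(ValueError, match="sample_interval"):
        simulate(ring6, DMFParams(), np.ones(6), 100.0, seed=0, sample_interval=0.25)


def test_wrong_noise_shape_rejected(ring6):
    with pytest.raises(ValueError, match="noise"):
        simulate(ring6, DMFParams(), np.ones(6), 100.0, seed=0,
                 noise=np.zeros((10, 2, 6)))


def test_trajectory_metadata(ring6):
    traj = simulate(ring6, DMFParams(), np.ones(6), 500.0, seed=1)
    assert traj.n_regions == 6
    assert traj.n_samples == 50
    assert traj.duration == pytest.approx(500.0)
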