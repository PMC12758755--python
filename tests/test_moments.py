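import numpy as np
import pytest
from scipy.integrate import solve_ivp

import gaitdyn as gd
from conftest import evaluate_trajectory, random_models


def finite_difference_forces(chain, models, t, cadence, ht=1e-5, hq=1e-5):
    """Energy-only Euler–Lagrange oracle: FD in time and in coordinates."""
    n = chain.geometry.n_coords

    def L_parts(tt):
        th, om, _ = evaluate_trajectory(models, tt, cadence)
        return th, om

    def momenta(th, om):
        out = np.zeros_like(om)
        for i in range(n):
            e = np.zeros((n, 1))
            e[i] = hq
            out[i] = (chain.kinetic_energy(th, om + e)
                      - chain.kinetic_energy(th, om - e)) / (2 * hq)
        return out

    th_p, om_p = L_parts(t + ht)
    th_m, om_m = L_parts(t - ht)
    dp_dt = (momenta(th_p, om_p) - momenta(th_m, om_m)) / (2 * ht)
    th0, om0 = L_parts(t)
    dL_dth = np.zeros_like(th0)
    for i in range(n):
        e = np.zeros((n, 1))
        e[i] = hq
        Lp = (chain.kinetic_energy(th0 + e, om0)
              - chain.potential_energy(th0 + e))
        Lm = (chain.kinetic_energy(th0 - e, om0)
              - chain.potential_energy(th0 - e))
        dL_dth[i] = (Lp - Lm) / (2 * hq)
    return dp_dt - dL_dth


def test_kinetic_energy_properties(segments):
    chain = gd.build_chain("single_support", segments)
    rng = np.random.default_rng(0)
    th = rng.normal(0, 0.4, (3, 10))
    om = rng.normal(0, 1.0, (3, 10))
    assert np.allclose(chain.kinetic_energy(th, np.zeros_like(om)), 0.0)
    T1 = chain.kinetic_energy(th, om)
    assert np.all(T1 >= 0)
    assert np.allclose(chain.kinetic_energy(th, 2 * om), 4 * T1, rtol=1e-12)


def test_potential_energy_at_upright_stack(segments):
    chain = gd.build_chain("single_support", segments)
    y = (segments.leg_mass * segments.p_1
         + segments.m * segments.l_1
         + segments.m_t * (segments.l_1 - segments.p_2)
         + segments.m_s * (segments.l_1 - segments.l_2 - segments.p_3))
    assert chain.potential_energy(np.zeros(3)) == pytest.approx(segments.g * y)


def test_single_pendulum_closed_form(subject, toy_table):
    # a one-coordinate hanging chain: Q = m p^2 thdd + m g p sin(th)
    seg = gd.build_segment_set(subject, toy_table)
    chain = gd.build_chain("single_support", seg)
    # isolate the swing-shank coordinate by freezing the others
    t = np.linspace(0, 1, 30)
    A, w = 0.4, 3.0
    th3 = A * np.sin(w * t)
    om3 = A * w * np.cos(w * t)
    al3 = -A * w**2 * np.sin(w * t)
    z = np.zeros_like(t)
    Q = gd.generalized_forces(chain, np.vstack([z, z, th3]),
                              np.vstack([z, z, om3]), np.vstack([z, z, al3]))
    expected = (seg.m_s * seg.p_3**2 * al3
                + seg.m_s * seg.g * seg.p_3 * np.sin(th3))
    assert np.max(np.abs(Q[2] - expected)) < 1e-9


def test_static_forces_equal_gravity_gradient(segments):
    chain = gd.build_chain("single_support", segments)
    rng = np.random.default_rng(4)
    th = rng.normal(0, 0.4, (3, 8))
    z = np.zeros_like(th)
    Q = gd.generalized_forces(chain, th, z, z)
    grad = -chain.g * chain.G[:, None] * np.sin(th)
    assert np.allclose(Q, grad, atol=1e-12)


@pytest.mark.parametrize("phase,n_coords", [("single_support", 3),
                                            ("double_support", 2)])
def test_generalized_forces_match_energy_oracle(segments, phase, n_coords):
    rng = np.random.default_rng(21)
    chain = gd.build_chain(phase, segments)
    t = np.linspace(0, 1, 17)
    models = random_models(rng, n_coords)
    th, om, al = evaluate_trajectory(models, t, 1.0)
    Q = gd.generalized_forces(chain, th, om, al)
    Q_fd = finite_difference_forces(chain, models, t, 1.0)
    assert np.max(np.abs(Q - Q_fd)) < 1e-4 * np.max(np.abs(Q))


def test_single_support_moment_chain(segments):
    rng = np.random.default_rng(8)
    chain = gd.build_chain("single_support", segments)
    t = np.linspace(0, 1, 15)
    th, om, al = evaluate_trajectory(random_models(rng, 3), t, 1.0)
    states = gd.chain_states_single(t, th, om, al, segments)
    mom = gd.single_support_moments(chain, states)
    Q = gd.generalized_forces(chain, th, om, al)
    assert np.allclose(mom["knee_swing"], Q[2])
    assert np.allclose(mom["knee_swing"] - mom["hip_swing"], Q[1])
    assert np.allclose(mom["hip_swing"] - mom["ankle_stance"], Q[0])


def test_static_upright_moments_vanish(segments):
    chain = gd.build_chain("single_support", segments)
    z = np.zeros((3, 1))
    states = gd.chain_states_single(np.zeros(1), z, z, z, segments)
    mom = gd.single_support_moments(chain, states)
    for series in mom.values():
        assert series[0] == pytest.approx(0.0, abs=1e-12)


def test_static_tilted_shank_knee_moment(segments):
    # only the swing shank tilted: M_k = m_s g p_3 sin(theta_3)
    chain = gd.build_chain("single_support", segments)
    th = np.array([[0.0], [0.0], [0.35]])
    z = np.zeros_like(th)
    states = gd.chain_states_single(np.zeros(1), th, z, z, segments)
    mom = gd.single_support_moments(chain, states)
    assert mom["knee_swing"][0] == pytest.approx(
        segments.m_s * segments.g * segments.p_3 * np.sin(0.35))


def test_double_support_static_split_stance_moments(segments):
    chain = gd.build_chain("double_support", segments)
    th1, th2 = -0.2, 0.3
    th = np.array([[th1], [th2]])
    z = np.zeros_like(th)
    states = gd.chain_states_double(np.zeros(1), th, z, z, segments)
    mom = gd.double_support_moments(chain, states)
    leg, m = segments.leg_mass, segments.m
    # gravity torques of the two-rod system about its own coordinates
    Q1 = -segments.g * (leg * segments.p_1 + (m + leg) * segments.l_1) * np.sin(th1)
    Q2 = segments.g * leg * segments.p_2d * np.sin(th2)
    assert mom["ankle_leading"][0] == pytest.approx(Q2)
    assert mom["hip_trailing"][0] == pytest.approx(Q2 - Q1)


def test_stance_knee_moment_lever_combination(segments):
    assert gd.stance_knee_moment(0.0, 0.0, segments) == pytest.approx(0.0)
    got = gd.stance_knee_moment(1.0, 1.0, segments)
    assert got == pytest.approx(
        segments.l_3 / segments.l_1 + segments.l_2 / segments.l_1)
    assert got == pytest.approx(1.0)  # l_2 + l_3 = l_1
    Ma, Mh = np.array([2.0, -1.0]), np.array([0.5, 3.0])
    expect = Ma * segments.l_3 / segments.l_1 + Mh * segments.l_2 / segments.l_1
    assert np.allclose(gd.stance_knee_moment(Ma, Mh, segments), expect)


def test_free_fall_conserves_energy(segments):
    # unforced double-support chain integrated forward: E stays constant
    chain = gd.build_chain("double_support", segments)

    def rhs(_, y):
        th, om = y[:2], y[2:]
        rest = gd.generalized_forces(chain, th[:, None], om[:, None],
                                     np.zeros((2, 1)))[:, 0]
        M = chain.mass_matrix(th)
        thdd = np.linalg.solve(M, -rest)
        return np.concatenate([om, thdd])

    y0 = np.array([0.3, -0.25, 0.4, 0.1])
    sol = solve_ivp(rhs, (0.0, 0.8), y0, rtol=1e-10, atol=1e-12,
                    dense_output=True)
    assert sol.success
    ts = np.linspace(0, 0.8, 20)
    E = []
    for tt in ts:
        th, om = sol.sol(tt)[:2], sol.sol(tt)[2:]
        E.append(chain.kinetic_energy(th, om) + chain.potential_energy(th))
    E = np.asarray(E)
    assert np.max(np.abs(E - E[0])) < 1e-7 * max(1.0, abs(E[0]))


def test_phase_mismatch_rejected(segments):
    chain_s = gd.build_chain("single_support", segments)
    z = np.zeros((2, 1))
    states_d = gd.chain_states_double(np.zeros(1), z, z, z, segments)
    with pytest.raises(ValueError):
        gd.single_support_moments(chain_s, states_d)
    chain_d = gd.build_chain("double_support", segments)
    z3 = np.zeros((3, 1))
    states_s = gd.chain_states_single(np.zeros(1), z3, z3, z3, segments)
    with pytest.raises(ValueError):
        gd.double_support_moments(chain_d, states_s)
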