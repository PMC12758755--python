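import numpy as np
import pytest

import gaitdyn as gd
from conftest import evaluate_trajectory, random_models, states_factory


def static_single(segments, theta=None, n=1):
    z = np.zeros((3, n))
    th = z if theta is None else np.tile(np.asarray(theta, float)[:, None], n)
    return gd.chain_states_single(np.zeros(n), th, z, z, segments)


def static_double(segments, theta=None, n=1):
    z = np.zeros((2, n))
    th = z if theta is None else np.tile(np.asarray(theta, float)[:, None], n)
    return gd.chain_states_double(np.zeros(n), th, z, z, segments)


def test_static_single_support_carries_body_weight(segments, subject):
    grf = gd.grf_single_support(static_single(segments), segments)
    assert grf.total_y[0] == pytest.approx(subject.body_mass * segments.g)
    assert grf.total_x[0] == pytest.approx(0.0)
    # cohort-mean mass in newtons
    assert grf.total_y[0] == pytest.approx(58.7 * 9.81)


def test_static_double_support_carries_body_weight(segments, subject):
    grf = gd.grf_double_support_total(static_double(segments, [-0.2, 0.3]),
                                      segments)
    assert grf.total_y[0] == pytest.approx(subject.body_mass * segments.g)
    assert grf.total_x[0] == pytest.approx(0.0)


def test_grf_scales_linearly_with_masses(subject, toy_table):
    rng = np.random.default_rng(11)
    seg1 = gd.build_segment_set(subject, toy_table)
    seg2 = gd.build_segment_set(
        gd.SubjectParams(subject.leg_length, 2 * subject.body_mass,
                         subject.cadence), toy_table)
    t = np.linspace(0, 1, 13)
    th, om, al = evaluate_trajectory(random_models(rng, 2), t, 1.0)
    g1 = gd.grf_double_support_total(
        gd.chain_states_double(t, th, om, al, seg1), seg1)
    g2 = gd.grf_double_support_total(
        gd.chain_states_double(t, th, om, al, seg2), seg2)
    assert np.allclose(g2.total_y, 2.0 * g1.total_y, rtol=1e-12)
    assert np.allclose(g2.total_x, 2.0 * g1.total_x, rtol=1e-12)


def test_momentum_rate_oracle_single_support(segments):
    rng = np.random.default_rng(2)
    T = 1.0
    t = np.linspace(0, T, 31)
    h = 1e-6 * T
    models = random_models(rng, 3)
    states = states_factory(models, 1.0, segments, "single_support")
    sp, sm, s0 = states(t + h), states(t - h), states(t)
    m = np.array([segments.leg_mass, segments.m, segments.m_t, segments.m_s])
    grf = gd.grf_single_support(s0, segments)
    dmom_y = (m @ sp.yd - m @ sm.yd) / (2 * h)
    dmom_x = (m @ sp.xd - m @ sm.xd) / (2 * h)
    lhs = grf.total_y - segments.total_mass * segments.g
    assert np.max(np.abs(lhs - dmom_y)) < 1e-4 * np.max(np.abs(lhs))
    assert np.max(np.abs(grf.total_x - dmom_x)) < 1e-4 * np.max(np.abs(grf.total_x))


def test_split_boundary_values_static(segments, subject):
    timing = gd.PhaseTiming(0.0, 0.12)
    weight = subject.body_mass * segments.g
    st = static_double(segments, n=2)
    st.times = np.array([0.0, 0.12])
    split = gd.split_double_support(st, segments, timing)
    # s = 0: trailing foot carries everything; s = 1: leading foot does
    assert split.trailing_y[0] == pytest.approx(weight)
    assert split.leading_y[0] == pytest.approx(0.0)
    assert split.trailing_y[1] == pytest.approx(0.0)
    assert split.leading_y[1] == pytest.approx(weight)


def test_vertical_split_sums_to_total(segments):
    rng = np.random.default_rng(9)
    t = np.linspace(0, 0.12, 25)
    th, om, al = evaluate_trajectory(random_models(rng, 2), t, 1.0)
    st = gd.chain_states_double(t, th, om, al, segments)
    timing = gd.PhaseTiming(0.0, 0.12)
    split = gd.split_double_support(st, segments, timing)
    assert np.max(np.abs(split.trailing_y + split.leading_y
                         - split.total_y)) < 1e-9


def test_horizontal_split_residual_matches_published_form(segments):
    # per-foot x forces sum to m*xdd_c + s*leg*(xdd_s1 + xdd_s2), not the total
    rng = np.random.default_rng(10)
    t = np.linspace(0, 0.12, 25)
    th, om, al = evaluate_trajectory(random_models(rng, 2), t, 1.0)
    st = gd.chain_states_double(t, th, om, al, segments)
    timing = gd.PhaseTiming(0.0, 0.12)
    split = gd.split_double_support(st, segments, timing)
    s = timing.transfer_fraction(t)
    i1, i2 = st.row("trailing_leg"), st.row("leading_leg")
    expected_sum = (segments.m * st.trunk()["xdd"]
                    + s * segments.leg_mass * (st.xdd[i1] + st.xdd[i2]))
    assert np.allclose(split.trailing_x + split.leading_x, expected_sum,
                       atol=1e-9)
    res = gd.horizontal_split_residual(split)
    assert np.allclose(res, expected_sum - split.total_x, atol=1e-9)
    # at s = 1 the residual closes
    assert abs(res[-1]) < 1e-9


def test_conserving_variant_differs_only_on_trailing_leg(segments):
    rng = np.random.default_rng(12)
    t = np.linspace(0, 0.12, 9)
    th, om, al = evaluate_trajectory(random_models(rng, 2), t, 1.0)
    st = gd.chain_states_double(t, th, om, al, segments)
    timing = gd.PhaseTiming(0.0, 0.12)
    printed = gd.split_double_support(st, segments, timing)
    cons = gd.split_double_support(st, segments, timing, conserving=True)
    assert np.allclose(printed.leading_x, cons.leading_x)
    assert not np.allclose(printed.trailing_x, cons.trailing_x)


def test_boundary_load_continuity_at_toeoff(segments):
    # at s = 1 the trailing gravity share is exactly zero
    rng = np.random.default_rng(13)
    t = np.linspace(0, 0.12, 13)
    th, om, al = evaluate_trajectory(random_models(rng, 2), t, 1.0)
    st = gd.chain_states_double(t, th, om, al, segments)
    split = gd.split_double_support(st, segments, gd.PhaseTiming(0.0, 0.12))
    i1 = st.row("trailing_leg")
    residual = (segments.m * st.trunk()["ydd"][-1] / 2.0
                + segments.leg_mass * st.ydd[i1, -1])
    assert split.trailing_y[-1] == pytest.approx(residual, abs=1e-9)


def test_times_outside_window_rejected(segments):
    st = static_double(segments, n=1)
    st.times = np.array([0.5])
    with pytest.raises(ValueError):
        gd.split_double_support(st, segments, gd.PhaseTiming(0.0, 0.12))


def test_phase_mismatch_rejected(segments):
    st = static_single(segments)
    with pytest.raises(ValueError):
        gd.grf_double_support_total(st, segments)
    std = static_double(segments)
    with pytest.raises(ValueError):
        gd.grf_single_support(std, segments)


def test_normalized_copy_divides_by_body_weight(segments, subject):
    grf = gd.grf_single_support(static_single(segments), segments)
    norm = grf.normalized(subject.body_mass, segments.g)
    assert norm.total_y[0] == pytest.approx(1.0)
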