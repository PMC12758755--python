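import numpy as np
import pytest

import gaitdyn as gd


@pytest.fixture
def toy_table():
    """Explicit toy fractions so no test depends on the shipped defaults."""
    return gd.AnthropometricTable(
        thigh_mass_fraction=0.10,
        shank_mass_fraction=0.05,
        thigh_length_fraction=0.53,
        shank_length_fraction=0.47,
        thigh_centroid_fraction=0.4,
        shank_centroid_fraction=0.4,
    )


@pytest.fixture
def subject():
    return gd.SubjectParams(leg_length=0.9, body_mass=58.7, cadence=0.9)


@pytest.fixture
def segments(subject, toy_table):
    return gd.build_segment_set(subject, toy_table)


@pytest.fixture(scope="session")
def default_cycle():
    """The shipped-default prediction, shared across tests (read-only)."""
    return gd.predict_cycle(gd.cohort_reference_subject())


def random_models(rng, n_coords, scale=0.2, n_harmonics=3):
    """Random smooth periodic coordinate models (Fourier trajectories)."""
    out = []
    for _ in range(n_coords):
        B = rng.normal(0.0, scale, n_harmonics + 1)
        phi = rng.uniform(-np.pi, np.pi, n_harmonics)
        out.append(gd.FourierAngleModel("coord", tuple(B), tuple(phi)))
    return out


def evaluate_trajectory(models, t, cadence, leg_length=1.0):
    """Stacked (theta, omega, alpha) arrays for a list of coordinate models."""
    theta = np.array([m.angle(t, leg_length, cadence) for m in models])
    om, al = [], []
    for m in models:
        d1, d2 = m.angle_derivatives(t, leg_length, cadence)
        om.append(d1)
        al.append(d2)
    return theta, np.array(om), np.array(al)


def states_factory(models, cadence, segments, phase):
    """Chain states as a function of the time grid (for shift-based FD oracles)."""
    build = (gd.chain_states_single if phase == "single_support"
             else gd.chain_states_double)

    def states(t):
        theta, om, al = evaluate_trajectory(models, t, cadence)
        return build(t, theta, om, al, segments)

    return states
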