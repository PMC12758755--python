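"""Planar linkage kinematics for the reduced lower-limb chains.

Coordinate convention (fixed here, used everywhere): the stance or
trailing foot's ground contact is the origin, x points anterior, y up.
Every segment angle theta is measured from the upward vertical, positive
when the distal end is anterior to the proximal end.  The supporting rod
rises from the ground (hip at ``(l1*sin(theta1), l1*cos(theta1))``);
swing segments hang from the hip, so with all angles zero the swing
thigh centroid sits at ``(0, l1 - p2)`` and the swing shank centroid at
``(0, l1 - l2 - p3)``.

Single support is a three-link chain (stance rod, swing thigh, swing
shank, plus a trunk point mass at the hip); double support rigidifies
each leg into one rod, giving a two-link chain (trailing rod carrying
the trunk at its tip, leading rod hanging from the hip).

Every point-mass position in either chain is a sum of terms
``(a_i*sin(theta_i), c_i*cos(theta_i))``, so the whole chain geometry is
two constant coefficient matrices ``A`` and ``C`` (one row per point
mass, one column per generalized coordinate).  Velocities and
accelerations are analytic derivatives; numeric differencing exists only
in test oracles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .anthropometry import SegmentSet

SINGLE_SUPPORT = "single_support"
DOUBLE_SUPPORT = "double_support"


@dataclass(frozen=True)
class ChainGeometry:
    """Point-mass chain: ``x_k = A[k] @ sin(theta)``, ``y_k = C[k] @ cos(theta)``."""

    phase: str
    masses: np.ndarray  # (k,)
    A: np.ndarray  # (k, n)
    C: np.ndarray  # (k, n)
    labels: tuple[str, ...]

    @property
    def n_coords(self) -> int:
        return self.A.shape[1]

    def positions(self, theta: np.ndarray):
        s, c = np.sin(theta), np.cos(theta)
        return self.A @ s, self.C @ c

    def velocities(self, theta, omega):
        s, c = np.sin(theta), np.cos(theta)
        return self.A @ (c * omega), -(self.C @ (s * omega))

    def accelerations(self, theta, omega, alpha):
        s, c = np.sin(theta), np.cos(theta)
        xdd = self.A @ (c * alpha - s * omega**2)
        ydd = -(self.C @ (s * alpha + c * omega**2))
        return xdd, ydd


def single_support_geometry(segments: SegmentSet) -> ChainGeometry:
    """Stance rod, trunk point, swing thigh, swing shank over (theta1..theta3)."""
    l1, l2 = segments.l_1, segments.l_2
    p1, p2, p3 = segments.p_1, segments.p_2, segments.p_3
    A = np.array([
        [p1, 0.0, 0.0],   # stance-rod centroid
        [l1, 0.0, 0.0],   # trunk point mass at the hip
        [l1, p2, 0.0],    # swing thigh centroid
        [l1, l2, p3],     # swing shank centroid
    ])
    C = np.array([
        [p1, 0.0, 0.0],
        [l1, 0.0, 0.0],
        [l1, -p2, 0.0],
        [l1, -l2, -p3],
    ])
    masses = np.array([segments.leg_mass, segments.m, segments.m_t, segments.m_s])
    return ChainGeometry(SINGLE_SUPPORT, masses, A, C,
                         ("stance_leg", "trunk", "swing_thigh", "swing_shank"))


def double_support_geometry(segments: SegmentSet) -> ChainGeometry:
    """Trailing rod, trunk point, leading rod over (theta_1d, theta_2d)."""
    l1, p1, p2d = segments.l_1, segments.p_1, segments.p_2d
    A = np.array([
        [p1, 0.0],    # trailing-leg centroid (from its ground contact)
        [l1, 0.0],    # trunk point mass at the hip
        [l1, p2d],    # leading-leg centroid (from the hip)
    ])
    C = np.array([
        [p1, 0.0],
        [l1, 0.0],
        [l1, -p2d],
    ])
    masses = np.array([segments.leg_mass, segments.m, segments.leg_mass])
    return ChainGeometry(DOUBLE_SUPPORT, masses, A, C,
                         ("trailing_leg", "trunk", "leading_leg"))


@dataclass
class SegmentStateSeries:
    """Centroid kinematics of every chain point mass on a common grid.

    Arrays are (n_masses, n_times); the trunk is one of the rows
    (``labels`` names them).  ``theta``/``omega``/``alpha_ang`` are the
    generalized-coordinate series (n_coords, n_times).
    """

    phase: str
    times: np.ndarray
    labels: tuple[str, ...]
    theta: np.ndarray
    omega: np.ndarray
    alpha_ang: np.ndarray
    x: np.ndarray
    y: np.ndarray
    xd: np.ndarray
    yd: np.ndarray
    xdd: np.ndarray
    ydd: np.ndarray

    def row(self, label: str) -> int:
        return self.labels.index(label)

    def trunk(self) -> dict[str, np.ndarray]:
        k = self.row("trunk")
        return {
            "x": self.x[k], "y": self.y[k],
            "xd": self.xd[k], "yd": self.yd[k],
            "xdd": self.xdd[k], "ydd": self.ydd[k],
        }


def segment_angles_from_joints(hip, knee):
    """Absolute swing-segment angles from hip and knee joint angles.

    With zero pelvic tilt the thigh-to-vertical angle equals the hip
    angle, and the shank angle is ``hip - knee`` (knee flexion swings
    the shank posterior).  Works on scalars or arrays; derivatives pass
    through the same linear map.
    """
    hip = np.asarray(hip, dtype=float)
    knee = np.asarray(knee, dtype=float)
    if hip.shape != knee.shape:
        raise ValueError("hip and knee series must share a time grid")
    return hip, hip - knee


def _states(geom: ChainGeometry, times, theta, omega, alpha) -> SegmentStateSeries:
    times = np.asarray(times, dtype=float)
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    omega = np.atleast_2d(np.asarray(omega, dtype=float))
    alpha = np.atleast_2d(np.asarray(alpha, dtype=float))
    if not (theta.shape == omega.shape == alpha.shape):
        raise ValueError("theta, omega, alpha must have identical shapes")
    if theta.shape[0] != geom.n_coords:
        raise ValueError(
            f"{geom.phase} expects {geom.n_coords} coordinate series, "
            f"got {theta.shape[0]}"
        )
    if theta.shape[1] != times.size:
        raise ValueError("angle series and time grid lengths differ")
    x, y = geom.positions(theta)
    xd, yd = geom.velocities(theta, omega)
    xdd, ydd = geom.accelerations(theta, omega, alpha)
    return SegmentStateSeries(
        phase=geom.phase, times=times, labels=geom.labels,
        theta=theta, omega=omega, alpha_ang=alpha,
        x=x, y=y, xd=xd, yd=yd, xdd=xdd, ydd=ydd,
    )


def chain_states_single(
    times, theta, omega, alpha, segments: SegmentSet
) -> SegmentStateSeries:
    """Kinematic state of the three-link single-support chain.

    ``theta`` rows: stance rod, swing thigh, swing shank (angles from
    vertical); ``omega``/``alpha`` their first/second time derivatives.
    """
    return _states(single_support_geometry(segments), times, theta, omega, alpha)


def chain_states_double(
    times, theta, omega, alpha, segments: SegmentSet
) -> SegmentStateSeries:
    """Kinematic state of the two-link double-support chain.

    ``theta`` rows: trailing rod, leading rod.
    """
    return _states(double_support_geometry(segments), times, theta, omega, alpha)


def foot_separation(states: SegmentStateSeries, segments: SegmentSet):
    """Diagnostic: horizontal trailing-to-leading foot distance in double support.

    The two rod angles are predicted independently, so the closed loop
    is not enforced; this exposes the implied step length
    ``l1*(sin(theta_2d) - ... )`` measured as the leading foot's x
    relative to the trailing contact at the origin.
    """
    if states.phase != DOUBLE_SUPPORT:
        raise ValueError("foot separation is defined in double support only")
    th1, th2 = states.theta
    return segments.l_1 * np.sin(th1) + segments.l_1 * np.sin(th2)
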