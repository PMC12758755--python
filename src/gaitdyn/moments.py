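"""Joint moments by Lagrangian inverse dynamics.

Each support chain is a planar point-mass system (segment masses at
their centroids, trunk lump at the hip; no segment rotational inertia).
With every point-mass position of the form ``(a_i sin(theta_i),
c_i cos(theta_i))`` summed over coordinates, the kinetic energy is
``T = 1/2 * omega' M(theta) omega`` with

    M_ij = alpha_ij cos(theta_i)cos(theta_j) + gamma_ij sin(theta_i)sin(theta_j)
    alpha = A' diag(m) A,   gamma = C' diag(m) C

and the potential is ``V = g * G . cos(theta)`` with ``G = m' C``.  The
Euler–Lagrange left-hand side then has the closed form

    Q_i = cos_i (alpha @ (cos * thdd))_i + sin_i (gamma @ (sin * thdd))_i
        - cos_i (alpha @ (sin * thd^2))_i + sin_i (gamma @ (cos * thd^2))_i
        - g G_i sin_i

(the velocity cross terms of d/dt(dT/dthd) and dT/dth cancel).  This is
the production path; finite differencing of the energies appears only in
test oracles.

Joint moments follow from the virtual-work chain of differences: in
single support the swing-knee moment equals the shank coordinate's
generalized force and the swing-hip and stance-ankle moments follow by
subtracting the thigh and stance-rod forces; in double support the
leading-ankle moment equals the leading rod's force and the trailing-hip
moment follows.  The stance-side knee moment is the lever-arm
combination ``M_k = M_a*l3/l1 + M_h*l2/l1`` of the same limb's ankle and
hip moments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .anthropometry import SegmentSet
from .linkage import (
    DOUBLE_SUPPORT,
    SINGLE_SUPPORT,
    ChainGeometry,
    SegmentStateSeries,
    double_support_geometry,
    single_support_geometry,
)

__all__ = [
    "LagrangianChain",
    "build_chain",
    "generalized_forces",
    "single_support_moments",
    "double_support_moments",
    "stance_knee_moment",
]


@dataclass(frozen=True)
class LagrangianChain:
    """Evaluable energies of one support chain."""

    geometry: ChainGeometry
    g: float
    alpha: np.ndarray  # (n, n)
    gamma: np.ndarray  # (n, n)
    G: np.ndarray  # (n,)

    @property
    def phase(self) -> str:
        return self.geometry.phase

    def mass_matrix(self, theta: np.ndarray) -> np.ndarray:
        """Configuration-dependent generalized mass matrix (one instant)."""
        s, c = np.sin(theta), np.cos(theta)
        return self.alpha * np.outer(c, c) + self.gamma * np.outer(s, s)

    def kinetic_energy(self, theta, omega):
        """T(theta, omega); vectorized over trailing time axes."""
        theta = np.asarray(theta, dtype=float)
        omega = np.asarray(omega, dtype=float)
        s, c = np.sin(theta), np.cos(theta)
        co = c * omega
        so = s * omega
        return 0.5 * (
            np.einsum("i...,ij,j...->...", co, self.alpha, co)
            + np.einsum("i...,ij,j...->...", so, self.gamma, so)
        )

    def potential_energy(self, theta):
        """V(theta) with the ground contact as zero potential."""
        theta = np.asarray(theta, dtype=float)
        return self.g * np.einsum("i,i...->...", self.G, np.cos(theta))


def build_chain(phase: str, segments: SegmentSet, g: float | None = None
                ) -> LagrangianChain:
    """Assemble the point-mass chain energies for one support phase."""
    if phase == SINGLE_SUPPORT:
        geom = single_support_geometry(segments)
    elif phase == DOUBLE_SUPPORT:
        geom = double_support_geometry(segments)
    else:
        raise ValueError(f"unknown phase {phase!r}")
    m = geom.masses
    return LagrangianChain(
        geometry=geom,
        g=segments.g if g is None else g,
        alpha=geom.A.T @ (m[:, None] * geom.A),
        gamma=geom.C.T @ (m[:, None] * geom.C),
        G=m @ geom.C,
    )


def generalized_forces(chain: LagrangianChain, theta, omega, alpha_ang):
    """Euler–Lagrange left-hand side along a trajectory, per coordinate.

    Inputs are (n_coords, n_times) arrays; returns the same shape.
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    omega = np.atleast_2d(np.asarray(omega, dtype=float))
    thdd = np.atleast_2d(np.asarray(alpha_ang, dtype=float))
    if not (theta.shape == omega.shape == thdd.shape):
        raise ValueError("theta, omega, alpha must share a shape")
    s, c = np.sin(theta), np.cos(theta)
    w2 = omega**2
    Q = (
        c * (chain.alpha @ (c * thdd))
        + s * (chain.gamma @ (s * thdd))
        - c * (chain.alpha @ (s * w2))
        + s * (chain.gamma @ (c * w2))
        - chain.g * chain.G[:, None] * s
    )
    return Q


def _forces_from_states(chain: LagrangianChain, states: SegmentStateSeries):
    if states.phase != chain.phase:
        raise ValueError(
            f"states are {states.phase} but chain is {chain.phase}"
        )
    return generalized_forces(chain, states.theta, states.omega, states.alpha_ang)


def single_support_moments(
    chain: LagrangianChain, states: SegmentStateSeries
) -> dict[str, np.ndarray]:
    """Swing-knee, swing-hip, and stance-ankle moment series (N·m).

    Solves the triangular chain of differences: ``M_k = Q_3``,
    ``M_k - M_h2 = Q_2``, ``M_h2 - M_a = Q_1``.
    """
    if chain.phase != SINGLE_SUPPORT:
        raise ValueError("chain is not the single-support chain")
    Q = _forces_from_states(chain, states)
    M_k = Q[2]
    M_h2 = M_k - Q[1]
    M_a = M_h2 - Q[0]
    return {"knee_swing": M_k, "hip_swing": M_h2, "ankle_stance": M_a}


def double_support_moments(
    chain: LagrangianChain, states: SegmentStateSeries
) -> dict[str, np.ndarray]:
    """Leading-ankle and trailing-hip moment series (N·m).

    ``M_a^leading = Q_2d``; ``M_a^leading - M_h^trailing = Q_1d``.
    """
    if chain.phase != DOUBLE_SUPPORT:
        raise ValueError("chain is not the double-support chain")
    Q = _forces_from_states(chain, states)
    M_a_lead = Q[1]
    M_h_trail = M_a_lead - Q[0]
    return {"ankle_leading": M_a_lead, "hip_trailing": M_h_trail}


def stance_knee_moment(M_a, M_h, segments: SegmentSet):
    """Stance-limb knee moment from the same limb's ankle and hip moments.

    ``M_k = M_a * l3/l1 + M_h * l2/l1``; valid in both stance sub-phases
    because the knee is rigid within the stance rod.
    """
    M_a = np.asarray(M_a, dtype=float)
    M_h = np.asarray(M_h, dtype=float)
    return M_a * (segments.l_3 / segments.l_1) + M_h * (segments.l_2 / segments.l_1)
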