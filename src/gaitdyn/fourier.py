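"""Fourier-series empirical joint-angle model.

The left hip or knee angle over one gait cycle is modelled as

    phi_L(t) = B0*l + sum_j  Bj*l * sin(2*pi*j*f*t + phi_j),   j = 1..n

with leg length ``l`` (m), cadence ``f`` (strides/s), amplitude
coefficients ``Bj`` (rad/m) and phases ``phi_j`` (rad).  The right-side
angle replaces ``phi_j`` with ``phi_j + j*pi``, which is exactly a
half-period time shift.  Hip and knee use three harmonics; an ankle
model would use four, but no ankle coefficients are shipped (the
dynamic chain treats each stance leg as a rigid rod and never needs
ankle kinematics).

All angles are radians internally; degrees appear only at file
boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .anthropometry import SubjectParams

__all__ = [
    "FourierAngleModel",
    "evaluate_angle",
    "angle_derivatives",
    "fit_fourier_coefficients",
    "default_angle_models",
    "FourierAngleRegressor",
]


@dataclass(frozen=True)
class FourierAngleModel:
    """Per-joint harmonic coefficients ``B_0..B_n`` and phases ``phi_1..phi_n``.

    Amplitudes are stored in the canonical signed form with every phase
    in (-pi/2, pi/2]; the sign of the amplitude disambiguates the
    remaining half-turn.  Under this convention the least-squares fitter
    returns a unique tuple for any non-degenerate signal.
    """

    joint: str
    B: tuple[float, ...]
    phi: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "B", tuple(float(b) for b in self.B))
        object.__setattr__(self, "phi", tuple(float(p) for p in self.phi))
        if len(self.B) < 2:
            raise ValueError("need at least one harmonic (B_0 and B_1)")
        if len(self.phi) != len(self.B) - 1:
            raise ValueError("phi must have one entry per harmonic")

    @property
    def n_harmonics(self) -> int:
        return len(self.phi)

    def _phases(self, side: str) -> np.ndarray:
        j = np.arange(1, self.n_harmonics + 1)
        phi = np.asarray(self.phi, dtype=float)
        if side == "left":
            return phi
        if side == "right":
            return phi + j * np.pi
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")

    def angle(self, t, leg_length: float, cadence: float, side: str = "left"):
        """Joint angle in radians at time(s) ``t`` (seconds)."""
        t = np.asarray(t, dtype=float)
        j = np.arange(1, self.n_harmonics + 1)
        arg = 2.0 * np.pi * j * cadence * t[..., None] + self._phases(side)
        B = np.asarray(self.B, dtype=float)
        out = leg_length * (B[0] + np.sin(arg) @ B[1:])
        return out if out.shape else float(out)

    def angle_derivatives(self, t, leg_length: float, cadence: float,
                          side: str = "left"):
        """Analytic first and second time derivatives (rad/s, rad/s^2)."""
        t = np.asarray(t, dtype=float)
        j = np.arange(1, self.n_harmonics + 1)
        w = 2.0 * np.pi * j * cadence
        arg = w * t[..., None] + self._phases(side)
        B = np.asarray(self.B[1:], dtype=float)
        d1 = leg_length * (np.cos(arg) @ (B * w))
        d2 = -leg_length * (np.sin(arg) @ (B * w**2))
        if d1.shape:
            return d1, d2
        return float(d1), float(d2)


def evaluate_angle(
    model: FourierAngleModel, subject: SubjectParams, t, side: str = "left"
):
    """Evaluate the empirical angle model for a subject (radians)."""
    return model.angle(t, subject.leg_length, subject.cadence, side)


def angle_derivatives(
    model: FourierAngleModel, subject: SubjectParams, t, side: str = "left"
):
    """Angular velocity and acceleration for a subject (rad/s, rad/s^2)."""
    return model.angle_derivatives(t, subject.leg_length, subject.cadence, side)


def _canonical_amplitude_phase(a: np.ndarray, b: np.ndarray):
    """Convert ``a*sin(x) + b*cos(x)`` to ``B*sin(x + phi)``.

    Canonical form: phi in (-pi/2, pi/2], B signed.  Zero harmonics map
    to (0, 0).
    """
    B = np.hypot(a, b)
    phi = np.arctan2(b, a)
    flip_up = phi > np.pi / 2
    flip_down = phi <= -np.pi / 2
    phi = np.where(flip_up, phi - np.pi, phi)
    phi = np.where(flip_down, phi + np.pi, phi)
    B = np.where(flip_up | flip_down, -B, B)
    zero = (a == 0.0) & (b == 0.0)
    return np.where(zero, 0.0, B), np.where(zero, 0.0, phi)


def fit_fourier_coefficients(
    times,
    angles,
    leg_length: float,
    cadence: float,
    n_harmonics: int = 3,
    joint: str = "joint",
) -> tuple[FourierAngleModel, float]:
    """Least-squares fit of the harmonic model to one angle series.

    Ordinary linear least squares on the basis
    ``{1, sin(2*pi*j*f*t), cos(2*pi*j*f*t)}``, then conversion to the
    canonical signed amplitude–phase form with amplitudes divided by the
    leg length (so the returned ``B`` are in rad/m and portable across
    subjects).

    Returns
    -------
    model : FourierAngleModel
    residual : float
        Root-mean-square reconstruction residual, radians.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(angles, dtype=float)
    if t.ndim != 1 or t.shape != y.shape:
        raise ValueError("times and angles must be 1-D arrays of equal length")
    if n_harmonics < 1:
        raise ValueError("n_harmonics must be >= 1")
    if leg_length <= 0 or cadence <= 0:
        raise ValueError("leg_length and cadence must be positive")
    n_params = 2 * n_harmonics + 1
    if t.size < n_params:
        raise ValueError(
            f"need at least {n_params} samples to fit {n_harmonics} harmonics"
        )
    j = np.arange(1, n_harmonics + 1)
    arg = 2.0 * np.pi * cadence * np.outer(t, j)
    X = np.column_stack([np.ones_like(t), np.sin(arg), np.cos(arg)])
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < n_params:
        raise ValueError(
            "rank-deficient design matrix: samples do not resolve "
            f"{n_harmonics} harmonics at cadence {cadence}"
        )
    a = coef[1 : n_harmonics + 1]
    b = coef[n_harmonics + 1 :]
    B_amp, phi = _canonical_amplitude_phase(a, b)
    B = np.concatenate([[coef[0]], B_amp]) / leg_length
    residual = float(np.sqrt(np.mean((X @ coef - y) ** 2)))
    return FourierAngleModel(joint=joint, B=tuple(B), phi=tuple(phi)), residual


def default_angle_models() -> dict[str, FourierAngleModel]:
    """Population hip and knee models for healthy adult level walking.

    Three-harmonic empirical coefficients (rad/m amplitudes, rad phases)
    estimated from a 10-subject healthy-adult cohort; shipped as the
    published prior, not re-estimated per subject.
    """
    return {
        "hip": FourierAngleModel(
            joint="hip",
            B=(0.086, -0.316, -0.067, 0.026),
            phi=(-1.105, 1.433, 0.187),
        ),
        "knee": FourierAngleModel(
            joint="knee",
            B=(0.468, 0.465, 0.311, -0.093),
            phi=(0.244, -0.990, 0.266),
        ),
    }


class FourierAngleRegressor(RegressorMixin, BaseEstimator):
    """scikit-learn estimator wrapping :func:`fit_fourier_coefficients`.

    ``X`` is a single column of time stamps (seconds) and ``y`` the
    joint angle in radians.  The cadence is a parameter, not estimated:
    the model is a harmonic regression at known stride frequency.

    Attributes
    ----------
    model_ : FourierAngleModel
        Fitted coefficients in canonical form.
    residual_ : float
        RMS reconstruction residual, radians.
    """

    def __init__(self, n_harmonics: int = 3, cadence: float = 1.0,
                 leg_length: float = 1.0, joint: str = "joint",
                 side: str = "left"):
        self.n_harmonics = n_harmonics
        self.cadence = cadence
        self.leg_length = leg_length
        self.joint = joint
        self.side = side

    @staticmethod
    def _times(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            return X
        if X.ndim == 2 and X.shape[1] == 1:
            return X[:, 0]
        raise ValueError("X must be a 1-D array or a single-column 2-D array")

    def fit(self, X, y):
        t = self._times(X)
        self.model_, self.residual_ = fit_fourier_coefficients(
            t, y, self.leg_length, self.cadence, self.n_harmonics, self.joint
        )
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        if not hasattr(self, "model_"):
            raise AttributeError("estimator is not fitted; call fit first")
        t = self._times(X)
        return self.model_.angle(t, self.leg_length, self.cadence, self.side)
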