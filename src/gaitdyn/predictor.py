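"""Top-level scikit-learn-style predictor.

`GaitPredictor` packages the whole pipeline — anthropometric scaling,
empirical angle models, chain kinematics, GRF models, inverse dynamics,
cycle assembly — behind the estimator protocol, so it composes with
sklearn model selection and cloning.  Each "sample" is one subject, a
row of (leg_length m, body_mass kg, cadence strides/s); `predict`
returns one assembled :class:`~gaitdyn.cycle.GaitCycle` per row.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .anthropometry import AnthropometricTable, SubjectParams
from .cycle import GaitCycle, PhaseSchedule, predict_cycle
from .fourier import FourierAngleModel, default_angle_models

__all__ = ["GaitPredictor"]


class GaitPredictor(BaseEstimator):
    """Predict full-cycle gait dynamics from three scalars per subject.

    Parameters
    ----------
    angle_models : dict[str, FourierAngleModel] or None
        Hip and knee harmonic models; ``None`` uses the shipped
        population coefficients.
    table : AnthropometricTable or None
        Body-segment fractions; ``None`` uses the shipped defaults.
    ds_fraction : float
        Double-support duration as a fraction of the cycle.
    resolution : int
        Samples per gait cycle (even).

    There is nothing to estimate from data — the angle models are a
    published prior — so ``fit`` only validates and freezes the
    configuration into fitted attributes (``models_``, ``table_``,
    ``schedule_``).
    """

    def __init__(
        self,
        angle_models: dict[str, FourierAngleModel] | None = None,
        table: AnthropometricTable | None = None,
        ds_fraction: float = 0.12,
        resolution: int = 100,
    ):
        self.angle_models = angle_models
        self.table = table
        self.ds_fraction = ds_fraction
        self.resolution = resolution

    def fit(self, X=None, y=None) -> "GaitPredictor":
        self.models_ = (default_angle_models() if self.angle_models is None
                        else dict(self.angle_models))
        self.table_ = self.table if self.table is not None else AnthropometricTable()
        self.schedule_ = PhaseSchedule(self.ds_fraction, self.resolution)
        return self

    def predict(self, X) -> list[GaitCycle]:
        """One GaitCycle per (leg_length, body_mass, cadence) row."""
        if not hasattr(self, "models_"):
            self.fit()
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError("X must be (n_subjects, 3): leg length, mass, cadence")
        return [
            predict_cycle(SubjectParams(*row), self.models_, self.table_,
                          self.schedule_)
            for row in X
        ]

    def predict_subject(self, subject: SubjectParams) -> GaitCycle:
        if not hasattr(self, "models_"):
            self.fit()
        return predict_cycle(subject, self.models_, self.table_, self.schedule_)
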