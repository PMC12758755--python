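"""Synthetic pseudo-measured gait trials.

Validation-style workflows compare a prediction with several walking
trials of one subject that are time-normalized and averaged into a
single representative cycle.  This module emulates that structure with
no external data: each trial is the predicted cycle plus independent,
seeded Gaussian noise per sample.  Default noise levels per signal
class: 1 degree on angles, 2% of body weight on GRFs, 0.02 N·m/kg on
moments.  This reproduces the statistical structure of trial averaging
(sd shrinking as 1/sqrt(n_trials)), not biomechanically realistic
inter-trial variability — real trials vary in timing and waveform shape,
not just additive noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cycle import GaitCycle

__all__ = ["TrialSet", "default_noise_sd", "generate_trials", "average_trials"]


@dataclass
class TrialSet:
    """``n_trials`` noisy copies of every cycle signal on one grid."""

    times: np.ndarray
    trials: dict[str, np.ndarray]  # signal -> (n_trials, n_samples)
    noise_sd: dict[str, float]
    seed: int

    @property
    def n_trials(self) -> int:
        return next(iter(self.trials.values())).shape[0]

    def signal_names(self) -> list[str]:
        return list(self.trials)


def default_noise_sd(cycle: GaitCycle) -> dict[str, float]:
    """Per-signal noise standard deviations in native units."""
    bw = cycle.subject.body_mass * cycle.segments.g
    out: dict[str, float] = {}
    for name in cycle.signals():
        if name.startswith("angle"):
            out[name] = np.deg2rad(1.0)
        elif name.startswith("grf"):
            out[name] = 0.02 * bw
        else:
            out[name] = 0.02 * cycle.subject.body_mass
    return out


def generate_trials(
    cycle: GaitCycle,
    n_trials: int = 8,
    noise_sd: dict[str, float] | float | None = None,
    seed: int = 0,
) -> TrialSet:
    """Simulate repeated walking trials of one subject.

    Same seed, same TrialSet, bit for bit.  ``noise_sd`` may be a single
    float applied to every signal, a per-signal dict (missing signals
    fall back to the defaults), or ``None`` for the defaults.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    signals = cycle.signals()
    defaults = default_noise_sd(cycle)
    if noise_sd is None:
        sd = defaults
    elif isinstance(noise_sd, dict):
        sd = {**defaults, **noise_sd}
    else:
        sd = {name: float(noise_sd) for name in signals}
    if any(v < 0 for v in sd.values()):
        raise ValueError("noise sd must be non-negative")
    rng = np.random.default_rng(seed)
    trials = {
        name: series + rng.normal(0.0, sd[name], size=(n_trials, series.size))
        for name, series in signals.items()
    }
    return TrialSet(times=cycle.times.copy(), trials=trials,
                    noise_sd={n: sd[n] for n in signals}, seed=seed)


def average_trials(trials: TrialSet) -> dict[str, np.ndarray]:
    """Pointwise mean across trials: the representative cycle."""
    if not trials.trials:
        raise ValueError("empty trial set")
    return {name: arr.mean(axis=0) for name, arr in trials.trials.items()}
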