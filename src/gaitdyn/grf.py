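"""Ground reaction forces from the chain kinematics.

Single support: straight Newton's second law on the whole body — the
vertical GRF is body weight plus the mass-weighted sum of vertical
centroid accelerations, and the anterior–posterior GRF is the
mass-weighted sum of horizontal accelerations.  Double support gives the
same totals over the two-rod chain.

The per-foot split in double support assumes body mass transfers
linearly from the trailing to the leading foot over the double-support
window: with transfer fraction ``s`` running 0 to 1, the trailing foot
carries ``(1-s)`` of the gravity load plus its own leg's inertial term
and half the trunk's, the leading foot the mirror image.  The
anterior–posterior split multiplies both legs' inertia terms by ``s`` as
published, which does not conserve the horizontal total mid-window; the
residual is exposed as a diagnostic, and a non-default conserving
variant ((1-s) weighting on the trailing leg) exists for sensitivity
analysis only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .anthropometry import SegmentSet
from .linkage import DOUBLE_SUPPORT, SINGLE_SUPPORT, SegmentStateSeries

__all__ = [
    "PhaseTiming",
    "GRFSeries",
    "grf_single_support",
    "grf_double_support_total",
    "split_double_support",
    "horizontal_split_residual",
]


@dataclass(frozen=True)
class PhaseTiming:
    """Double-support window: leading heel strike to trailing toe off."""

    t_heelstrike: float
    t_toeoff: float

    def __post_init__(self) -> None:
        if not self.t_toeoff > self.t_heelstrike:
            raise ValueError("toe-off must follow heel strike")

    @property
    def duration(self) -> float:
        return self.t_toeoff - self.t_heelstrike

    def transfer_fraction(self, times) -> np.ndarray:
        """Linear mass-transfer fraction s(t) in [0, 1] on the window."""
        t = np.asarray(times, dtype=float)
        s = (t - self.t_heelstrike) / self.duration
        if np.any(s < -1e-9) or np.any(s > 1.0 + 1e-9):
            raise ValueError("times fall outside the double-support window")
        return np.clip(s, 0.0, 1.0)


@dataclass
class GRFSeries:
    """GRF series in newtons on a common grid.

    ``total_y``/``total_x`` are whole-body; the per-foot fields are
    populated by the double-support split (trailing = s1, leading = s2)
    and are ``None`` otherwise.
    """

    times: np.ndarray
    total_y: np.ndarray
    total_x: np.ndarray
    trailing_y: np.ndarray | None = None
    leading_y: np.ndarray | None = None
    trailing_x: np.ndarray | None = None
    leading_x: np.ndarray | None = None

    def normalized(self, body_mass: float, g: float) -> "GRFSeries":
        """Copy with every force divided by body weight (dimensionless)."""
        bw = body_mass * g
        sc = lambda a: None if a is None else a / bw
        return GRFSeries(self.times, self.total_y / bw, self.total_x / bw,
                         sc(self.trailing_y), sc(self.leading_y),
                         sc(self.trailing_x), sc(self.leading_x))


def _weighted_acc(states: SegmentStateSeries, segments: SegmentSet):
    """Mass-weighted sums of centroid accelerations (x and y)."""
    m = {
        SINGLE_SUPPORT: [segments.leg_mass, segments.m, segments.m_t, segments.m_s],
        DOUBLE_SUPPORT: [segments.leg_mass, segments.m, segments.leg_mass],
    }[states.phase]
    m = np.asarray(m)
    return m @ states.xdd, m @ states.ydd


def grf_single_support(states: SegmentStateSeries, segments: SegmentSet) -> GRFSeries:
    """Total GRF while one foot is on the ground (swing foot carries zero)."""
    if states.phase != SINGLE_SUPPORT:
        raise ValueError("expected single-support states")
    fx, fy = _weighted_acc(states, segments)
    weight = segments.total_mass * segments.g
    return GRFSeries(states.times, weight + fy, fx)


def grf_double_support_total(
    states: SegmentStateSeries, segments: SegmentSet
) -> GRFSeries:
    """Whole-body GRF during double support (both feet combined)."""
    if states.phase != DOUBLE_SUPPORT:
        raise ValueError("expected double-support states")
    fx, fy = _weighted_acc(states, segments)
    weight = segments.total_mass * segments.g
    return GRFSeries(states.times, weight + fy, fx)


def split_double_support(
    states: SegmentStateSeries,
    segments: SegmentSet,
    timing: PhaseTiming,
    conserving: bool = False,
) -> GRFSeries:
    """Per-foot GRF during double support via linear mass transfer.

    Vertical components sum to the two-rod total identically.  The
    published horizontal split weights both legs' inertia terms by the
    transfer fraction ``s`` and is implemented as such by default;
    ``conserving=True`` switches the trailing leg to ``1-s`` (sensitivity
    variant, not the published model).
    """
    if states.phase != DOUBLE_SUPPORT:
        raise ValueError("expected double-support states")
    s = timing.transfer_fraction(states.times)
    g, m = segments.g, segments.m
    leg = segments.leg_mass
    weight = segments.total_mass * g

    i_trail = states.row("trailing_leg")
    i_lead = states.row("leading_leg")
    tr = states.trunk()
    ydd_c, xdd_c = tr["ydd"], tr["xdd"]
    ydd_s1, ydd_s2 = states.ydd[i_trail], states.ydd[i_lead]
    xdd_s1, xdd_s2 = states.xdd[i_trail], states.xdd[i_lead]

    trailing_y = weight * (1.0 - s) + m * ydd_c / 2.0 + leg * ydd_s1
    leading_y = weight * s + m * ydd_c / 2.0 + leg * ydd_s2

    s_trail = (1.0 - s) if conserving else s
    trailing_x = (m - m * s) * xdd_c / 2.0 + leg * s_trail * xdd_s1
    leading_x = (m + m * s) * xdd_c / 2.0 + leg * s * xdd_s2

    total = grf_double_support_total(states, segments)
    return GRFSeries(states.times, total.total_y, total.total_x,
                     trailing_y, leading_y, trailing_x, leading_x)


def horizontal_split_residual(split: GRFSeries) -> np.ndarray:
    """Diagnostic: per-foot horizontal forces minus the two-rod total.

    Zero only where the transfer fraction is 1 (and at samples where the
    leg inertia terms vanish); nonzero mid-window by construction of the
    published split.
    """
    if split.trailing_x is None or split.leading_x is None:
        raise ValueError("series has no per-foot split")
    return split.trailing_x + split.leading_x - split.total_x
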