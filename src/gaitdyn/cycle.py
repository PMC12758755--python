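"""Full gait-cycle assembly.

One stride runs 0–100% from left heel strike.  The default schedule is
the standard partition: first double support 0–12% (left leg leading,
right trailing), first single support 12–50% (left stance, right swing),
then the mirror image.  Because the model assumes perfectly symmetric
periodic gait, only the first half cycle is computed; the second half is
the first with the legs swapped, so every right-side series equals the
left-side series rotated by exactly half the grid.

Within each window the matching chain is used: double support routes
through the two-rod chain, the linear mass-transfer GRF split, and the
two-coordinate inverse dynamics; single support through the three-link
chain, whole-body Newton GRF (swing foot carries zero), and the
three-coordinate inverse dynamics.  Stance-limb knee moments use the
lever-arm combination of the same limb's ankle and hip moments; hip
moments not determined by the reduced chains (stance side in single
support, leading side in double support) are closed by taking the two
limbs' hip moments equal and opposite (torque balance of the point-mass,
zero-tilt pelvis), and the trailing-limb ankle moment in double support
is outside the model and reported as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .anthropometry import (
    AnthropometricTable,
    SegmentSet,
    SubjectParams,
    build_segment_set,
)
from .fourier import FourierAngleModel, default_angle_models
from .grf import PhaseTiming, grf_single_support, split_double_support
from .linkage import chain_states_double, chain_states_single
from .moments import (
    build_chain,
    double_support_moments,
    single_support_moments,
    stance_knee_moment,
)

__all__ = [
    "PhaseSchedule",
    "GaitCycle",
    "predict_cycle",
    "transition_discontinuity",
    "cohort_reference_subject",
]

PHASES = ("ds1", "ss1", "ds2", "ss2")


def cohort_reference_subject() -> SubjectParams:
    """A representative healthy adult: 0.90 m leg, 58.7 kg, 0.9 strides/s."""
    return SubjectParams(leg_length=0.90, body_mass=58.7, cadence=0.90)


@dataclass(frozen=True)
class PhaseSchedule:
    """Phase partition of the normalized cycle.

    ``ds_fraction`` is the duration of each double-support phase as a
    fraction of the cycle (default 0.12, leaving 0.38 per single
    support).  Intervals are half-open, so with the default resolution
    of 100 samples exactly 12 fall in each double support.  The
    resolution must be even so the half-cycle mirror is an integer
    shift.
    """

    ds_fraction: float = 0.12
    resolution: int = 100

    def __post_init__(self) -> None:
        if not 0.0 < self.ds_fraction < 0.5:
            raise ValueError("ds_fraction must lie in (0, 0.5)")
        if self.resolution < 10 or self.resolution % 2:
            raise ValueError("resolution must be an even integer >= 10")

    @property
    def ss_fraction(self) -> float:
        return 0.5 - self.ds_fraction

    def intervals(self) -> list[tuple[str, float, float]]:
        d = self.ds_fraction
        return [("ds1", 0.0, d), ("ss1", d, 0.5),
                ("ds2", 0.5, 0.5 + d), ("ss2", 0.5 + d, 1.0)]

    def labels(self) -> np.ndarray:
        """Phase label of each of the ``resolution`` grid samples."""
        frac = np.arange(self.resolution) / self.resolution
        out = np.empty(self.resolution, dtype=object)
        for name, lo, hi in self.intervals():
            out[(frac >= lo) & (frac < hi)] = name
        return out.astype(str)


@dataclass
class GaitCycle:
    """Assembled per-limb kinematics and kinetics over one stride.

    Series dictionaries are keyed ``(side, name)`` with side 'left' or
    'right'.  Angles are radians, GRFs newtons, moments N·m; normalized
    copies are available through :meth:`grf_bw` and
    :meth:`moments_per_kg`.
    """

    subject: SubjectParams
    schedule: PhaseSchedule
    segments: SegmentSet
    times: np.ndarray
    phase: np.ndarray
    angles: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    grf: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    moments: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    @property
    def percent(self) -> np.ndarray:
        return 100.0 * self.times * self.subject.cadence

    def grf_bw(self) -> dict[tuple[str, str], np.ndarray]:
        """GRFs normalized to body weight (dimensionless)."""
        bw = self.subject.body_mass * self.segments.g
        return {k: v / bw for k, v in self.grf.items()}

    def moments_per_kg(self) -> dict[tuple[str, str], np.ndarray]:
        """Moments normalized to body mass (N·m/kg)."""
        return {k: v / self.subject.body_mass for k, v in self.moments.items()}

    def signals(self) -> dict[str, np.ndarray]:
        """Flat view of every series, keyed e.g. ``grf_left_vertical``."""
        out: dict[str, np.ndarray] = {}
        for (side, joint), v in self.angles.items():
            out[f"angle_{side}_{joint}"] = v
        for (side, comp), v in self.grf.items():
            out[f"grf_{side}_{comp}"] = v
        for (side, joint), v in self.moments.items():
            out[f"moment_{side}_{joint}"] = v
        return out


def _mirror(left_half: np.ndarray, right_half: np.ndarray):
    """Full-cycle left/right series from first-half series of both legs."""
    return (np.concatenate([left_half, right_half]),
            np.concatenate([right_half, left_half]))


def predict_cycle(
    subject: SubjectParams,
    models: dict[str, FourierAngleModel] | None = None,
    table: AnthropometricTable | None = None,
    schedule: PhaseSchedule | None = None,
) -> GaitCycle:
    """Predict angles, per-foot GRFs, and joint moments over one stride.

    The only subject inputs are leg length, body mass, and cadence; the
    angle models and anthropometric table default to the shipped
    population values.
    """
    if models is None:
        models = default_angle_models()
    if schedule is None:
        schedule = PhaseSchedule()
    for joint in ("hip", "knee"):
        if joint not in models:
            raise ValueError(f"models must provide a {joint!r} entry")
    segments = build_segment_set(subject, table)

    N = schedule.resolution
    T = subject.period
    times = np.arange(N) * (T / N)
    n_half = N // 2
    t_half = times[:n_half]
    frac = np.arange(n_half) / N
    ds_mask = frac < schedule.ds_fraction
    t_ds, t_ss = t_half[ds_mask], t_half[~ds_mask]

    # Joint angles and analytic derivatives, both legs, first half cycle.
    ang: dict[tuple[str, str], np.ndarray] = {}
    vel: dict[tuple[str, str], np.ndarray] = {}
    acc: dict[tuple[str, str], np.ndarray] = {}
    for side in ("left", "right"):
        for joint in ("hip", "knee"):
            m = models[joint]
            ang[side, joint] = m.angle(t_half, subject.leg_length,
                                       subject.cadence, side)
            d1, d2 = m.angle_derivatives(t_half, subject.leg_length,
                                         subject.cadence, side)
            vel[side, joint] = d1
            acc[side, joint] = d2

    def window(series, mask):
        return series[mask]

    # --- double support (left leading, right trailing) --------------------
    def rod(side, sign, mask):
        return (sign * window(ang[side, "hip"], mask),
                sign * window(vel[side, "hip"], mask),
                sign * window(acc[side, "hip"], mask))

    th1, om1, al1 = rod("right", -1.0, ds_mask)   # trailing rod
    th2, om2, al2 = rod("left", +1.0, ds_mask)    # leading rod
    states_d = chain_states_double(
        t_ds, np.vstack([th1, th2]), np.vstack([om1, om2]),
        np.vstack([al1, al2]), segments,
    )
    timing = PhaseTiming(0.0, schedule.ds_fraction * T)
    split = split_double_support(states_d, segments, timing)
    chain_d = build_chain("double_support", segments)
    mom_d = double_support_moments(chain_d, states_d)
    M_a_lead, M_h_trail = mom_d["ankle_leading"], mom_d["hip_trailing"]

    # --- single support (left stance, right swing) ------------------------
    th_st = -window(ang["left", "hip"], ~ds_mask)
    om_st = -window(vel["left", "hip"], ~ds_mask)
    al_st = -window(acc["left", "hip"], ~ds_mask)
    hipR = window(ang["right", "hip"], ~ds_mask)
    kneeR = window(ang["right", "knee"], ~ds_mask)
    states_s = chain_states_single(
        t_ss,
        np.vstack([th_st, hipR, hipR - kneeR]),
        np.vstack([om_st, window(vel["right", "hip"], ~ds_mask),
                   window(vel["right", "hip"], ~ds_mask)
                   - window(vel["right", "knee"], ~ds_mask)]),
        np.vstack([al_st, window(acc["right", "hip"], ~ds_mask),
                   window(acc["right", "hip"], ~ds_mask)
                   - window(acc["right", "knee"], ~ds_mask)]),
        segments,
    )
    grf_s = grf_single_support(states_s, segments)
    chain_s = build_chain("single_support", segments)
    mom_s = single_support_moments(chain_s, states_s)
    M_a, M_h2, M_k = (mom_s["ankle_stance"], mom_s["hip_swing"],
                      mom_s["knee_swing"])

    # --- stitch first-half signals per leg --------------------------------
    def stitch(ds_part, ss_part):
        out = np.empty(n_half)
        out[ds_mask] = ds_part
        out[~ds_mask] = ss_part
        return out

    zeros_ds = np.zeros(ds_mask.sum())
    zeros_ss = np.zeros((~ds_mask).sum())

    left_half = {
        ("grf", "vertical"): stitch(split.leading_y, grf_s.total_y),
        ("grf", "anterior_posterior"): stitch(split.leading_x, grf_s.total_x),
        ("moment", "ankle"): stitch(M_a_lead, M_a),
        ("moment", "hip"): stitch(-M_h_trail, -M_h2),
        ("moment", "knee"): stitch(
            stance_knee_moment(M_a_lead, -M_h_trail, segments),
            stance_knee_moment(M_a, -M_h2, segments),
        ),
    }
    right_half = {
        ("grf", "vertical"): stitch(split.trailing_y, zeros_ss),
        ("grf", "anterior_posterior"): stitch(split.trailing_x, zeros_ss),
        ("moment", "ankle"): stitch(zeros_ds, zeros_ss),
        ("moment", "hip"): stitch(M_h_trail, M_h2),
        ("moment", "knee"): stitch(
            stance_knee_moment(zeros_ds, M_h_trail, segments), M_k
        ),
    }
    for joint in ("hip", "knee"):
        left_half["angle", joint] = ang["left", joint]
        right_half["angle", joint] = ang["right", joint]

    cycle = GaitCycle(
        subject=subject, schedule=schedule, segments=segments,
        times=times, phase=schedule.labels(),
    )
    for key in left_half:
        kind, name = key
        left_full, right_full = _mirror(left_half[key], right_half[key])
        store = {"grf": cycle.grf, "moment": cycle.moments,
                 "angle": cycle.angles}[kind]
        store["left", name] = left_full
        store["right", name] = right_full
    return cycle


def transition_discontinuity(cycle: GaitCycle, normalized: bool = False):
    """Jump of every signal at each of the four phase boundaries.

    Returns ``(boundaries, jumps)``: the boundary positions in percent
    of the cycle, and a dict mapping flat signal names to the absolute
    difference between the first sample of each phase and the last
    sample of the preceding one (cyclically).  With ``normalized=True``
    GRFs are in body weight and moments in N·m/kg; angles stay radians.
    """
    phase = cycle.phase
    N = phase.size
    starts = [k for k in range(N) if phase[k] != phase[k - 1]]
    boundaries = np.array([100.0 * k / N for k in starts])
    if normalized:
        sig = GaitCycle(
            cycle.subject, cycle.schedule, cycle.segments, cycle.times,
            cycle.phase, cycle.angles, cycle.grf_bw(), cycle.moments_per_kg(),
        ).signals()
    else:
        sig = cycle.signals()
    for comp in ("vertical", "anterior_posterior"):
        sig[f"grf_total_{comp}"] = (
            sig[f"grf_left_{comp}"] + sig[f"grf_right_{comp}"]
        )
    jumps = {
        name: np.array([abs(v[k] - v[k - 1]) for k in starts])
        for name, v in sig.items()
    }
    return boundaries, jumps
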