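"""Subject parameters and body-segment anthropometry.

The dynamic model reduces the body to point masses: two legs (thigh +
shank per limb) and a single trunk lump (trunk, head, upper limbs, and
— because the model has no foot segment — the feet).  Segment masses,
lengths and centroid offsets are obtained from the subject's body mass
and ASIS-to-medial-malleolus leg length through a table of dimensionless
fractions, in the style of standard body-segment-parameter tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

GRAVITY = 9.81
"""Gravitational acceleration in m/s^2 (overridable wherever it is used)."""


@dataclass(frozen=True)
class SubjectParams:
    """The three measured inputs of the predictive model.

    Parameters
    ----------
    leg_length : float
        ASIS to medial malleolus distance, meters.
    body_mass : float
        Total body mass, kg.
    cadence : float
        Walking cadence in strides per second; the gait period is
        ``T = 1 / cadence``.
    """

    leg_length: float
    body_mass: float
    cadence: float

    def __post_init__(self) -> None:
        for name in ("leg_length", "body_mass", "cadence"):
            value = getattr(self, name)
            if not value > 0:
                raise ValueError(f"{name} must be positive, got {value!r}")

    @property
    def period(self) -> float:
        """Gait-cycle duration in seconds."""
        return 1.0 / self.cadence


@dataclass(frozen=True)
class AnthropometricTable:
    """Dimensionless body-segment fractions.

    Mass fractions are per limb (fractions of total body mass), length
    fractions are fractions of the measured leg length, and centroid
    fractions are measured from the proximal end of the segment.

    The shipped defaults are Dempster-type adult values (thigh 0.100 and
    shank 0.0465 of body mass per limb, segment centroids at 0.433 of
    segment length from the proximal joint) with a 0.53/0.47 thigh/shank
    split of the leg length.  They are configuration, not ground truth:
    override them with population-specific values where available.

    ``stance_leg_centroid_fraction`` locates the centroid of the whole
    leg treated as one rigid rod, measured from the ground contact as a
    fraction of leg length.  When ``None`` it is derived as the
    mass-weighted centroid of the thigh + shank implied by the other
    fractions.  ``leading_leg_centroid_fraction`` (distance of the
    leading double-support rod's centroid from the hip, fraction of leg
    length) defaults to the mirror image of the stance rod's value.
    """

    thigh_mass_fraction: float = 0.100
    shank_mass_fraction: float = 0.0465
    thigh_length_fraction: float = 0.53
    shank_length_fraction: float = 0.47
    thigh_centroid_fraction: float = 0.433
    shank_centroid_fraction: float = 0.433
    stance_leg_centroid_fraction: float | None = None
    leading_leg_centroid_fraction: float | None = None
    gravity: float = GRAVITY

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "gravity":
                continue
            value = getattr(self, f.name)
            if value is None:
                continue
            if not 0.0 < value < 1.0:
                raise ValueError(f"{f.name} must lie in (0, 1), got {value!r}")
        if 2.0 * (self.thigh_mass_fraction + self.shank_mass_fraction) >= 1.0:
            raise ValueError(
                "limb mass fractions leave no trunk mass: "
                "2*(thigh + shank) must be < 1"
            )
        if abs(self.thigh_length_fraction + self.shank_length_fraction - 1.0) > 1e-9:
            raise ValueError("thigh and shank length fractions must sum to 1")
        if not self.gravity > 0:
            raise ValueError("gravity must be positive")

    def derived_stance_centroid_fraction(self) -> float:
        """Mass-weighted whole-leg centroid, from the ground contact.

        Distances from the hip: thigh centroid at c_t*f_t of leg length,
        shank centroid at f_t + c_s*f_s.  The rod centroid from the
        ground is one minus the mass-weighted mean of those.
        """
        from_hip_thigh = self.thigh_centroid_fraction * self.thigh_length_fraction
        from_hip_shank = (
            self.thigh_length_fraction
            + self.shank_centroid_fraction * self.shank_length_fraction
        )
        m_t, m_s = self.thigh_mass_fraction, self.shank_mass_fraction
        from_hip = (m_t * from_hip_thigh + m_s * from_hip_shank) / (m_t + m_s)
        return 1.0 - from_hip


@dataclass(frozen=True)
class SegmentSet:
    """Dimensional segment parameters for one subject.

    Masses in kg, lengths/offsets in meters.  ``l_1`` is the rigid
    stance/double-support rod (the full leg), ``l_2``/``l_3`` thigh and
    shank.  ``p_1`` is measured from the ground contact, ``p_2`` from
    the hip, ``p_3`` from the knee, and ``p_2d`` (leading leg in double
    support) from the hip.
    """

    m_t: float
    m_s: float
    m: float
    l_1: float
    l_2: float
    l_3: float
    p_1: float
    p_2: float
    p_3: float
    p_2d: float
    g: float = GRAVITY

    def __post_init__(self) -> None:
        if self.m <= 0:
            raise ValueError("trunk mass must be positive")
        for name in ("m_t", "m_s", "l_1", "l_2", "l_3", "g"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if abs(self.l_2 + self.l_3 - self.l_1) > 1e-9 * self.l_1:
            raise ValueError("l_2 + l_3 must equal l_1")
        if not 0 < self.p_2 < self.l_2:
            raise ValueError("p_2 must lie inside the thigh")
        if not 0 < self.p_3 < self.l_3:
            raise ValueError("p_3 must lie inside the shank")
        if not 0 < self.p_1 < self.l_1:
            raise ValueError("p_1 must lie inside the leg")
        if not 0 < self.p_2d < self.l_1:
            raise ValueError("p_2d must lie inside the leg")

    @property
    def leg_mass(self) -> float:
        """Mass of one whole leg (thigh + shank), kg."""
        return self.m_t + self.m_s

    @property
    def total_mass(self) -> float:
        return self.m + 2.0 * self.leg_mass


def build_segment_set(
    subject: SubjectParams, table: AnthropometricTable | None = None
) -> SegmentSet:
    """Scale the anthropometric fractions to one subject.

    Mass is conserved exactly: ``m + 2*(m_t + m_s) == body_mass``; so is
    length: ``l_2 + l_3 == leg_length``.
    """
    if table is None:
        table = AnthropometricTable()
    M, L = subject.body_mass, subject.leg_length
    m_t = M * table.thigh_mass_fraction
    m_s = M * table.shank_mass_fraction
    m = M - 2.0 * (m_t + m_s)
    l_2 = L * table.thigh_length_fraction
    l_3 = L - l_2
    p_1_frac = (
        table.stance_leg_centroid_fraction
        if table.stance_leg_centroid_fraction is not None
        else table.derived_stance_centroid_fraction()
    )
    p_2d_frac = (
        table.leading_leg_centroid_fraction
        if table.leading_leg_centroid_fraction is not None
        else 1.0 - p_1_frac
    )
    return SegmentSet(
        m_t=m_t,
        m_s=m_s,
        m=m,
        l_1=L,
        l_2=l_2,
        l_3=l_3,
        p_1=L * p_1_frac,
        p_2=l_2 * table.thigh_centroid_fraction,
        p_3=l_3 * table.shank_centroid_fraction,
        p_2d=L * p_2d_frac,
        g=table.gravity,
    )


# ---------------------------------------------------------------------------
# plain-text key=value configuration


def table_to_config(table: AnthropometricTable) -> str:
    """Serialize a table as ``key = value`` lines."""
    lines = []
    for f in fields(table):
        value = getattr(table, f.name)
        if value is None:
            continue
        lines.append(f"{f.name} = {value!r}")
    return "\n".join(lines) + "\n"


def table_from_config(text: str) -> AnthropometricTable:
    """Parse a ``key = value`` configuration (``#`` starts a comment)."""
    known = {f.name for f in fields(AnthropometricTable)}
    kwargs: dict[str, float] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"line {lineno}: expected 'key = value', got {raw!r}")
        key, _, value = line.partition("=")
        key = key.strip()
        if key not in known:
            raise ValueError(f"line {lineno}: unknown key {key!r}")
        kwargs[key] = float(value.strip())
    return AnthropometricTable(**kwargs)


def load_table(path) -> AnthropometricTable:
    with open(path) as fh:
        return table_from_config(fh.read())


def save_table(table: AnthropometricTable, path) -> None:
    with open(path, "w") as fh:
        fh.write(table_to_config(table))


def with_gravity(table: AnthropometricTable, g: float) -> AnthropometricTable:
    return replace(table, gravity=g)
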