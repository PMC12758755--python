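"""CSV and plain-text interfaces.

Angles are stored in degrees in files (the field's reporting convention)
and radians in memory; GRFs in newtons with a body-weight-normalized
column; moments in N·m with an N·m/kg column.  All files carry a header
row.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .cycle import GaitCycle
from .fourier import FourierAngleModel

__all__ = [
    "write_cycle",
    "read_signals",
    "write_coefficients",
    "read_coefficients",
    "read_angle_series",
]


def write_cycle(cycle: GaitCycle, outdir) -> list[str]:
    """Write angles.csv, grf.csv, moments.csv, phases.csv; return paths."""
    os.makedirs(outdir, exist_ok=True)
    pct = cycle.percent
    paths = []

    rows = [
        {"percent_gait": p, "joint": joint, "side": side,
         "value_deg": np.degrees(v)}
        for (side, joint), series in sorted(cycle.angles.items())
        for p, v in zip(pct, series)
    ]
    paths.append(os.path.join(outdir, "angles.csv"))
    pd.DataFrame(rows).to_csv(paths[-1], index=False)

    bw = cycle.subject.body_mass * cycle.segments.g
    rows = [
        {"percent_gait": p, "foot": side, "component": comp,
         "value_N": v, "value_bw": v / bw}
        for (side, comp), series in sorted(cycle.grf.items())
        for p, v in zip(pct, series)
    ]
    paths.append(os.path.join(outdir, "grf.csv"))
    pd.DataFrame(rows).to_csv(paths[-1], index=False)

    M = cycle.subject.body_mass
    rows = [
        {"percent_gait": p, "joint": joint, "side": side,
         "value_Nm": v, "value_Nm_per_kg": v / M}
        for (side, joint), series in sorted(cycle.moments.items())
        for p, v in zip(pct, series)
    ]
    paths.append(os.path.join(outdir, "moments.csv"))
    pd.DataFrame(rows).to_csv(paths[-1], index=False)

    paths.append(os.path.join(outdir, "phases.csv"))
    pd.DataFrame({"percent_gait": pct, "phase": cycle.phase}).to_csv(
        paths[-1], index=False
    )
    return paths


def read_signals(directory) -> dict[str, np.ndarray]:
    """Read a cycle directory back into flat signal arrays.

    Returns keys like ``angle_left_hip`` (radians), ``grf_left_vertical``
    (newtons), ``moment_left_ankle`` (N·m), each sorted by percent_gait.
    Missing files are skipped.
    """
    out: dict[str, np.ndarray] = {}

    def pull(path, group_cols, value_col, prefix, transform=None):
        if not os.path.exists(path):
            return
        df = pd.read_csv(path)
        for keys, sub in df.groupby(group_cols, sort=True):
            sub = sub.sort_values("percent_gait")
            vals = sub[value_col].to_numpy(dtype=float)
            if transform is not None:
                vals = transform(vals)
            name = "_".join([prefix, *map(str, np.atleast_1d(keys))])
            out[name] = vals

    pull(os.path.join(directory, "angles.csv"), ["side", "joint"],
         "value_deg", "angle", np.radians)
    pull(os.path.join(directory, "grf.csv"), ["foot", "component"],
         "value_N", "grf")
    pull(os.path.join(directory, "moments.csv"), ["side", "joint"],
         "value_Nm", "moment")
    return out


def read_angle_series(path, joint: str | None = None, side: str = "left"):
    """One (percent, radians) series from an angles.csv-format file."""
    df = pd.read_csv(path)
    if joint is not None:
        df = df[df["joint"] == joint]
    if "side" in df.columns:
        df = df[df["side"] == side]
    if df.empty:
        raise ValueError(f"no rows for joint={joint!r}, side={side!r}")
    df = df.sort_values("percent_gait")
    return (df["percent_gait"].to_numpy(dtype=float),
            np.radians(df["value_deg"].to_numpy(dtype=float)))


def write_coefficients(models: dict[str, FourierAngleModel], path) -> None:
    """Plain-text coefficient table: joint, n, B_0..B_n, phi_1..phi_n."""
    n_max = max(m.n_harmonics for m in models.values())
    cols = (["joint", "n"] + [f"B_{k}" for k in range(n_max + 1)]
            + [f"phi_{k}" for k in range(1, n_max + 1)])
    rows = []
    for name, m in sorted(models.items()):
        row: dict[str, object] = {"joint": name, "n": m.n_harmonics}
        row.update({f"B_{k}": b for k, b in enumerate(m.B)})
        row.update({f"phi_{k}": p for k, p in enumerate(m.phi, start=1)})
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_coefficients(path) -> dict[str, FourierAngleModel]:
    df = pd.read_csv(path)
    out: dict[str, FourierAngleModel] = {}
    for _, row in df.iterrows():
        n = int(row["n"])
        B = tuple(float(row[f"B_{k}"]) for k in range(n + 1))
        phi = tuple(float(row[f"phi_{k}"]) for k in range(1, n + 1))
        out[str(row["joint"])] = FourierAngleModel(str(row["joint"]), B, phi)
    return out
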