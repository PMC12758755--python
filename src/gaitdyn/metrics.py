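"""Waveform agreement metrics: RMSE, relative RMSE, Pearson correlation.

The relative RMSE normalizes by the *measured* signal's range and is
reported in percent, matching how gait-prediction errors are tabulated.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["rmse", "rrmse", "pearson", "metrics_report"]


def _pair(predicted, measured):
    p = np.asarray(predicted, dtype=float)
    m = np.asarray(measured, dtype=float)
    if p.ndim != 1 or p.shape != m.shape:
        raise ValueError("predicted and measured must be 1-D and equal length")
    if p.size == 0:
        raise ValueError("empty series")
    return p, m


def rmse(predicted, measured) -> float:
    """Root-mean-square error, in the series' native units."""
    p, m = _pair(predicted, measured)
    return float(np.sqrt(np.mean((p - m) ** 2)))


def rrmse(predicted, measured) -> float:
    """RMSE as a percentage of the measured signal's range."""
    p, m = _pair(predicted, measured)
    span = float(np.max(m) - np.min(m))
    if span == 0.0:
        raise ValueError("measured signal is constant; rRMSE is undefined")
    return 100.0 * rmse(p, m) / span


def pearson(predicted, measured) -> float:
    """Pearson correlation between the two waveforms."""
    p, m = _pair(predicted, measured)
    if p.size < 2 or np.ptp(p) == 0.0 or np.ptp(m) == 0.0:
        raise ValueError("Pearson correlation needs two non-constant series")
    return float(stats.pearsonr(p, m).statistic)


def metrics_report(
    predicted: dict[str, np.ndarray], measured: dict[str, np.ndarray]
) -> pd.DataFrame:
    """Per-signal metrics table for matching signal dictionaries.

    Rows: signal, rmse, rrmse_percent, pearson_rho, n.  Signals present
    in only one of the inputs are skipped; constant measured signals get
    NaN rRMSE/rho rather than an error.
    """
    rows = []
    for name in predicted:
        if name not in measured:
            continue
        p, m = _pair(predicted[name], measured[name])
        try:
            rr = rrmse(p, m)
        except ValueError:
            rr = np.nan
        try:
            rho = pearson(p, m)
        except ValueError:
            rho = np.nan
        rows.append({
            "signal": name, "rmse": rmse(p, m), "rrmse_percent": rr,
            "pearson_rho": rho, "n": p.size,
        })
    return pd.DataFrame(rows)


def absolute_error_series(predicted, measured) -> np.ndarray:
    """Per-sample |predicted - measured|, for external waveform statistics."""
    p, m = _pair(predicted, measured)
    return np.abs(p - m)
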