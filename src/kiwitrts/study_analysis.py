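"""Phenotype indices and storage-time correlation tables.

Color indices follow the single-ratio colorimetric conventions
(Chroma = sqrt(a*^2 + b*^2), Hue = arctan(b*/a*) in degrees); note the hue
here deliberately uses the printed one-argument ratio form, which folds
quadrants (a* < 0 gives the same hue as the mirrored point) — see
docs/methods.md.  Correlations are Pearson product-moment r between a
measured quantity and storage day, computed per fruit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

__all__ = [
    "chroma",
    "hue",
    "ab_ratio",
    "correlate_with_time",
    "build_correlation_table",
    "CORRELATION_COLUMNS",
]

CORRELATION_COLUMNS = (
    "L_star",
    "a_star",
    "b_star",
    "ab_ratio",
    "chroma",
    "hue",
    "mu_s_prime",
    "mu_a",
    "pc1_score",
)


def chroma(a_star: float, b_star: float) -> float:
    """Chromatic intensity: Euclidean norm of (a*, b*)."""
    return float(np.hypot(a_star, b_star))


def hue(a_star: float, b_star: float) -> float:
    """Hue angle arctan(b*/a*) in degrees, range (-90, 90)."""
    if a_star == 0:
        raise ValueError("hue undefined for a_star = 0 under the ratio convention")
    return float(np.degrees(np.arctan(b_star / a_star)))


def ab_ratio(a_star: float, b_star: float) -> float:
    """The a*/b* redness-to-yellowness ratio."""
    if b_star == 0:
        raise ValueError("ab_ratio undefined for b_star = 0")
    return float(a_star / b_star)


def correlate_with_time(days: np.ndarray, measurements: np.ndarray) -> float:
    """Pearson r between storage day and a repeated measurement."""
    d = np.asarray(days, dtype=float)
    m = np.asarray(measurements, dtype=float)
    if d.size != m.size or d.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(d) == 0 or np.ptp(m) == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(pearsonr(d, m)[0])


def _safe_r(days: np.ndarray, values: np.ndarray) -> float:
    mask = np.isfinite(values) & np.isfinite(days)
    if mask.sum() < 3:
        return np.nan
    d, v = days[mask], values[mask]
    if np.ptp(d) == 0 or np.ptp(v) == 0:
        return np.nan
    return float(pearsonr(d, v)[0])


def build_correlation_table(records: pd.DataFrame) -> pd.DataFrame:
    """Per-fruit Pearson correlations of each parameter with storage day.

    ``records`` holds one row per (sample, day) with columns ``sample_id``,
    ``day``, the CIELAB channels, and optionally ``mu_s_prime``, ``mu_a``
    and ``pc1_score``.  The derived color indices are computed row-wise
    first.  Cells whose parameter is missing or degenerate (fewer than 3
    finite pairs, or zero variance) are reported as NaN — absent, never 0.
    """
    req = {"sample_id", "day", "L_star", "a_star", "b_star"}
    missing = req - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")

    df = records.copy()
    a = df["a_star"].to_numpy(float)
    b = df["b_star"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        df["ab_ratio"] = np.where(b != 0, a / b, np.nan)
        df["chroma"] = np.hypot(a, b)
        df["hue"] = np.where(a != 0, np.degrees(np.arctan(b / a)), np.nan)

    rows = []
    for sid, grp in df.groupby("sample_id", sort=False):
        grp = grp.sort_values("day")
        days = grp["day"].to_numpy(float)
        row = {"sample_id": sid}
        for col in CORRELATION_COLUMNS:
            if col in grp.columns:
                row[col] = _safe_r(days, grp[col].to_numpy(float))
            else:
                row[col] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")
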