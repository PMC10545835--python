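"""Readers and writers for the shared CSV dialects.

TRPs and IRFs are two-column UTF-8 CSVs with header ``time_ps,counts`` and a
"." decimal separator; the study manifest is a flat CSV with one row per
(sample, day) measurement.  All readers validate on load and raise named
parse errors rather than propagating malformed data.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .instrument import InstrumentResponse, TimeGrid, TimeResolvedProfile
from .synthetic_data import MANIFEST_COLUMNS, StudyDataset

__all__ = [
    "read_trp_csv",
    "write_trp_csv",
    "read_irf_csv",
    "read_manifest",
    "read_study",
]


def _read_time_series(path: str) -> tuple[TimeGrid, np.ndarray]:
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["time_ps", "counts"]:
        raise ValueError(
            f"{path}: expected header 'time_ps,counts', got {list(df.columns)}"
        )
    t = df["time_ps"].to_numpy(float)
    c = df["counts"].to_numpy(float)
    if t.size < 8:
        raise ValueError(f"{path}: fewer than 8 rows")
    steps = np.diff(t)
    dt = steps.mean()
    if dt <= 0 or np.any(np.abs(steps - dt) > 1e-6 * abs(dt)):
        raise ValueError(f"{path}: time grid is not uniform")
    bad = np.where(np.isnan(c) | (c < 0))[0]
    if bad.size:
        raise ValueError(
            f"{path}: negative or NaN counts at row {int(bad[0]) + 2} "
            "(1-based, counting the header)"
        )
    grid = TimeGrid(t0=float(t[0]), dt=float(dt), n_bins=int(t.size))
    return grid, c


def read_trp_csv(path: str, meta: dict | None = None) -> TimeResolvedProfile:
    """Load a TRP from a two-column CSV, validating grid uniformity."""
    grid, counts = _read_time_series(path)
    return TimeResolvedProfile(grid=grid, counts=counts, meta=dict(meta or {}))


def write_trp_csv(path: str, profile: TimeResolvedProfile) -> None:
    pd.DataFrame({"time_ps": profile.grid.times, "counts": profile.counts}).to_csv(
        path, index=False
    )


def read_irf_csv(path: str) -> InstrumentResponse:
    """Load an IRF from the same CSV dialect; weights are renormalized."""
    grid, counts = _read_time_series(path)
    return InstrumentResponse(grid=grid, weights=counts)


def read_manifest(path: str) -> pd.DataFrame:
    """Load and validate the study manifest."""
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
    return df


def read_study(directory: str, require_truth: bool = False) -> StudyDataset:
    """Load a fixture directory written by :func:`~kiwitrts.synthetic_data.write_fixture`."""
    manifest_path = os.path.join(directory, "manifest.csv")
    records = read_manifest(manifest_path)
    irf = read_irf_csv(os.path.join(directory, "irf.csv"))
    trps = {}
    for row in records.itertuples():
        trp_file = os.path.join(directory, row.trp_path)
        if not os.path.exists(trp_file):
            raise FileNotFoundError(
                f"manifest references missing TRP for sample {row.sample_id} "
                f"day {row.day}: {trp_file}"
            )
        meta = {
            "sample_id": row.sample_id,
            "condition": row.condition,
            "day": row.day,
        }
        trps[(row.sample_id, row.day)] = read_trp_csv(trp_file, meta)
    truth_path = os.path.join(directory, "truth.csv")
    if os.path.exists(truth_path):
        truth = pd.read_csv(truth_path)
    elif require_truth:
        raise FileNotFoundError(f"{truth_path} not found")
    else:
        truth = pd.DataFrame()
    return StudyDataset(records=records, trps=trps, irf=irf, truth=truth)
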