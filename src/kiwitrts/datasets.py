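"""Published optical-property tables from a kiwifruit storage experiment.

Per-fruit estimates of the absorption coefficient mu_a and reduced
scattering coefficient mu_s' at 846 nm for ten 'Hayward' kiwifruit followed
through shelf-life storage (days 0, 1, 3, 5, 7, 9, 11, 13) and another ten
through cold storage (days 0, 7, ..., 49), as tabulated in the originating
storage study.  These serve as worked-example inputs for the correlation
analysis: recomputing Pearson r between storage day and the mu_s' row of a
fruit reproduces the published per-fruit correlation values.

Also included are the published per-fruit correlation coefficients between
mu_s' (and mu_a) and storage time, rounded to 2 decimal places as printed,
for cross-checking.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "SHELF_LIFE_DAYS",
    "COLD_STORAGE_DAYS",
    "shelf_life_table",
    "cold_storage_table",
    "published_mu_s_day_correlations",
]

SHELF_LIFE_DAYS = (0, 1, 3, 5, 7, 9, 11, 13)
COLD_STORAGE_DAYS = (0, 7, 14, 21, 28, 35, 42, 49)

# rows: samples 1..10; columns: the storage-day grid above
_SHELF_MU_A = np.array([
    [0.015, 0.021, 0.011, 0.011, 0.010, 0.012, 0.018, 0.007],
    [0.008, 0.007, 0.006, 0.004, 0.005, 0.005, 0.006, 0.006],
    [0.008, 0.009, 0.011, 0.008, 0.007, 0.010, 0.008, 0.008],
    [0.009, 0.011, 0.010, 0.006, 0.011, 0.011, 0.010, 0.011],
    [0.011, 0.007, 0.008, 0.007, 0.005, 0.008, 0.008, 0.005],
    [0.008, 0.014, 0.015, 0.011, 0.008, 0.007, 0.007, 0.008],
    [0.013, 0.011, 0.008, 0.007, 0.009, 0.008, 0.007, 0.008],
    [0.011, 0.010, 0.005, 0.008, 0.005, 0.013, 0.011, 0.012],
    [0.011, 0.007, 0.010, 0.007, 0.010, 0.007, 0.006, 0.008],
    [0.011, 0.012, 0.010, 0.009, 0.011, 0.009, 0.008, 0.009],
])

_SHELF_MU_S = np.array([
    [1.011, 0.965, 0.796, 0.512, 0.471, 0.709, 0.713, 0.426],
    [0.730, 0.340, 0.333, 0.243, 0.289, 0.358, 0.292, 0.250],
    [0.664, 0.668, 0.534, 0.456, 0.430, 0.503, 0.435, 0.456],
    [0.753, 0.959, 0.584, 0.426, 0.712, 0.552, 0.553, 0.547],
    [0.890, 0.506, 0.475, 0.436, 0.532, 0.391, 0.349, 0.386],
    [0.638, 0.704, 0.662, 0.529, 0.484, 0.411, 0.450, 0.583],
    [0.831, 0.567, 0.457, 0.483, 0.482, 0.437, 0.374, 0.395],
    [0.757, 0.629, 0.575, 0.681, 0.421, 0.583, 0.689, 0.620],
    [0.707, 0.471, 0.532, 0.394, 0.441, 0.380, 0.437, 0.336],
    [0.760, 0.621, 0.661, 0.510, 0.596, 0.497, 0.454, 0.508],
])

_COLD_MU_A = np.array([
    [0.008, 0.004, 0.008, 0.005, 0.011, 0.003, 0.005, 0.003],
    [0.006, 0.010, 0.011, 0.007, 0.006, 0.006, 0.010, 0.011],
    [0.010, 0.041, 0.013, 0.010, 0.012, 0.018, 0.008, 0.008],
    [0.018, 0.014, 0.017, 0.010, 0.014, 0.009, 0.010, 0.008],
    [0.009, 0.014, 0.013, 0.011, 0.012, 0.020, 0.011, 0.007],
    [0.009, 0.016, 0.007, 0.006, 0.009, 0.008, 0.008, 0.010],
    [0.008, 0.022, 0.013, 0.013, 0.009, 0.008, 0.009, 0.006],
    [0.023, 0.007, 0.010, 0.004, 0.006, 0.006, 0.006, 0.006],
    [0.007, 0.006, 0.007, 0.004, 0.006, 0.005, 0.004, 0.004],
    [0.013, 0.007, 0.011, 0.008, 0.007, 0.004, 0.011, 0.006],
])

_COLD_MU_S = np.array([
    [0.573, 0.458, 0.549, 0.335, 0.440, 0.331, 0.324, 0.294],
    [0.523, 0.557, 0.735, 0.419, 0.501, 0.409, 0.448, 0.374],
    [0.505, 1.800, 0.742, 0.612, 0.784, 1.000, 0.654, 0.594],
    [1.000, 0.704, 0.706, 0.497, 0.560, 0.358, 0.341, 0.333],
    [0.553, 1.154, 1.058, 0.738, 0.974, 1.145, 0.860, 0.676],
    [0.532, 0.653, 0.471, 0.408, 0.480, 0.387, 0.475, 0.410],
    [0.659, 0.739, 0.479, 0.608, 0.431, 0.411, 0.454, 0.444],
    [1.146, 0.372, 0.537, 0.297, 0.307, 0.260, 0.297, 0.257],
    [0.481, 0.380, 0.473, 0.378, 0.333, 0.368, 0.286, 0.255],
    [0.809, 0.460, 0.740, 0.500, 0.520, 0.460, 0.690, 0.420],
])

# published per-fruit Pearson r vs storage time (2 dp as printed)
_SHELF_R_MU_S = (-0.74, -0.60, -0.81, -0.58, -0.72, -0.68, -0.78, -0.23, -0.77, -0.84)
_SHELF_R_MU_A = (-0.46, -0.49, -0.33, 0.27, -0.61, -0.62, -0.68, 0.33, -0.47, -0.76)
_COLD_R_MU_S = (-0.86, -0.63, -0.29, -0.53, -0.83, -0.65, -0.78, -0.72, -0.88, -0.48)
_COLD_R_MU_A = (-0.41, 0.20, -0.43, -0.48, -0.43, -0.23, -0.56, -0.65, -0.86, -0.49)


def _table(mu_a: np.ndarray, mu_s: np.ndarray, days: tuple) -> pd.DataFrame:
    frames = []
    for name, arr in (("mu_a", mu_a), ("mu_s_prime", mu_s)):
        df = pd.DataFrame(
            arr,
            index=pd.Index(range(1, 11), name="sample"),
            columns=pd.Index(days, name="day"),
        )
        df.columns = pd.MultiIndex.from_product([[name], df.columns])
        frames.append(df)
    return pd.concat(frames, axis=1)


def shelf_life_table() -> pd.DataFrame:
    """Tabulated (mu_a, mu_s') per fruit and day under shelf-life storage."""
    return _table(_SHELF_MU_A, _SHELF_MU_S, SHELF_LIFE_DAYS)


def cold_storage_table() -> pd.DataFrame:
    """Tabulated (mu_a, mu_s') per fruit and day under cold storage."""
    return _table(_COLD_MU_A, _COLD_MU_S, COLD_STORAGE_DAYS)


def published_mu_s_day_correlations() -> pd.DataFrame:
    """Published per-fruit Pearson r between mu_s'/mu_a and storage time."""
    rows = []
    for cond, rs, ra in (
        ("shelf", _SHELF_R_MU_S, _SHELF_R_MU_A),
        ("cold", _COLD_R_MU_S, _COLD_R_MU_A),
    ):
        for i, (s, a) in enumerate(zip(rs, ra), start=1):
            rows.append(
                {"condition": cond, "sample": i, "r_mu_s_prime": s, "r_mu_a": a}
            )
    return pd.DataFrame(rows)
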