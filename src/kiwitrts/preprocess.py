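"""TRP preprocessing: smoothing, background removal, day-0 difference spectra.

Difference spectra (day d minus day 0, per fruit) remove the initial quality
variation between fruit so that downstream PCA picks up the storage-induced
change in the time-resolved profile rather than fruit-to-fruit offsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .instrument import TimeGrid, TimeResolvedProfile

__all__ = [
    "DifferenceProfile",
    "savitzky_golay_smooth",
    "subtract_background",
    "difference_profile",
]


@dataclass
class DifferenceProfile:
    """Per-bin count difference between a day-d and the day-0 TRP of one fruit."""

    grid: TimeGrid
    delta_counts: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.delta_counts = np.asarray(self.delta_counts, dtype=float)
        if self.delta_counts.shape != (self.grid.n_bins,):
            raise ValueError("delta_counts length must equal n_bins")
        if np.any(np.isnan(self.delta_counts)):
            raise ValueError("delta_counts contain NaN")


def savitzky_golay_smooth(
    profile: TimeResolvedProfile, poly_order: int = 2, frame_length: int = 5
) -> TimeResolvedProfile:
    """Savitzky-Golay local least-squares polynomial smoothing of a TRP.

    The defaults (quadratic, 5-point frame) give the classic interior weights
    (-3, 12, 17, 12, -3)/35; edges are handled by evaluating the polynomial
    fitted on the truncated end window.  Negative excursions introduced by
    the filter are clamped at zero so the result remains a valid TRP.
    """
    if frame_length % 2 == 0 or frame_length <= poly_order:
        raise ValueError("frame_length must be odd and > poly_order")
    if profile.grid.n_bins < frame_length:
        raise ValueError("profile shorter than frame_length")
    smoothed = savgol_filter(
        profile.counts, window_length=frame_length, polyorder=poly_order, mode="interp"
    )
    return TimeResolvedProfile(
        grid=profile.grid, counts=np.clip(smoothed, 0.0, None), meta=dict(profile.meta)
    )


def subtract_background(
    profile: TimeResolvedProfile, baseline_window: tuple[int, int]
) -> TimeResolvedProfile:
    """Remove a constant dark-count floor estimated from a pre-pulse window.

    ``baseline_window`` is a (start, stop) bin range that should precede the
    rising edge of the pulse; its mean is subtracted everywhere and negative
    bins are clamped at zero.
    """
    lo, hi = baseline_window
    if not (0 <= lo < hi <= profile.grid.n_bins):
        raise ValueError(f"invalid baseline window {baseline_window}")
    level = float(profile.counts[lo:hi].mean())
    peak = float(profile.counts.max())
    if peak > 0 and level > 0.5 * peak:
        warnings.warn(
            "baseline window mean exceeds half the peak: window likely overlaps "
            "the pulse",
            stacklevel=2,
        )
    corrected = np.clip(profile.counts - level, 0.0, None)
    return TimeResolvedProfile(grid=profile.grid, counts=corrected, meta=dict(profile.meta))


def difference_profile(
    profile_day_d: TimeResolvedProfile, profile_day_0: TimeResolvedProfile
) -> DifferenceProfile:
    """Day-d minus day-0 counts for the same fruit on the same grid.

    The result's metadata carries the (sample id, day, condition) of the
    day-d profile.  Antisymmetric by construction: diff(a, b) = -diff(b, a).
    """
    if profile_day_d.grid != profile_day_0.grid:
        raise ValueError("profiles are on different grids")
    sid_d = profile_day_d.meta.get("sample_id")
    sid_0 = profile_day_0.meta.get("sample_id")
    if sid_d is not None and sid_0 is not None and sid_d != sid_0:
        raise ValueError(f"sample mismatch: {sid_d!r} vs {sid_0!r}")
    return DifferenceProfile(
        grid=profile_day_d.grid,
        delta_counts=profile_day_d.counts - profile_day_0.counts,
        meta=dict(profile_day_d.meta),
    )
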