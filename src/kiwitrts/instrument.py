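"""Time grids, photon-count histograms, IRF handling, and counting noise.

The measurement chain is a streak camera recording a histogram of photon
arrival times ("time-resolved profile", TRP) over a ~5 ns window at ~10 ps
resolution.  What the camera records is the true slab response convolved
with the instrument response function (IRF); model fitting therefore always
goes through :func:`convolve_with_irf`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TimeGrid",
    "DEFAULT_GRID",
    "TimeResolvedProfile",
    "InstrumentResponse",
    "make_gaussian_irf",
    "estimate_fwhm",
    "convolve_with_irf",
    "simulate_counts",
]


@dataclass(frozen=True)
class TimeGrid:
    """Uniform time axis: times = t0 + k*dt for k in 0..n_bins-1 (ps)."""

    t0: float = 0.0
    dt: float = 10.3
    n_bins: int = 486

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if self.n_bins < 8:
            raise ValueError("n_bins must be >= 8")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_bins)

    @property
    def span(self) -> tuple[float, float]:
        return self.t0, self.t0 + self.dt * (self.n_bins - 1)

    def compatible_spacing(self, other: "TimeGrid", rtol: float = 1e-9) -> bool:
        return abs(self.dt - other.dt) <= rtol * self.dt


#: Default analysis grid mirroring the streak-camera settings:
#: 10.3 ps bins spanning ~5 ns.
DEFAULT_GRID = TimeGrid()


@dataclass
class TimeResolvedProfile:
    """Photon-count histogram on a uniform time grid.

    ``meta`` carries free-form labels (sample id, storage day, condition).
    """

    grid: TimeGrid
    counts: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (self.grid.n_bins,):
            raise ValueError(
                f"counts length {self.counts.shape} != n_bins {self.grid.n_bins}"
            )
        if np.any(np.isnan(self.counts)):
            raise ValueError("counts contain NaN")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def total_counts(self) -> float:
        return float(self.counts.sum())


@dataclass
class InstrumentResponse:
    """Normalized IRF on a uniform grid; weights sum to 1."""

    grid: TimeGrid
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (self.grid.n_bins,):
            raise ValueError("weights length must equal n_bins")
        if np.any(w < 0) or np.any(np.isnan(w)):
            raise ValueError("weights must be nonnegative and finite")
        total = w.sum()
        if total <= 0:
            raise ValueError("IRF weights are all zero")
        self.weights = w / total


def make_gaussian_irf(
    grid: TimeGrid, fwhm: float = 159.83, center: float | None = None
) -> InstrumentResponse:
    """Discretized Gaussian IRF with the given FWHM (ps), unit sum.

    A Gaussian stand-in for the measured response of the streak camera plus
    laser pulse; the default FWHM matches a typical measured system response.
    """
    if not fwhm > 0:
        raise ValueError("fwhm must be positive")
    lo, hi = grid.span
    if center is None:
        center = lo + 3.0 * fwhm
    if not (lo <= center <= hi):
        raise ValueError(f"center {center} outside grid span {grid.span}")
    if fwhm < 2 * grid.dt:
        warnings.warn(
            f"IRF fwhm {fwhm} ps is under-resolved on a {grid.dt} ps grid",
            stacklevel=2,
        )
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    t = grid.times
    w = np.exp(-0.5 * ((t - center) / sigma) ** 2)
    return InstrumentResponse(grid=grid, weights=w)


def estimate_fwhm(irf: InstrumentResponse) -> float:
    """Full width at half maximum (ps) by linear interpolation at half peak."""
    w = irf.weights
    peak = int(np.argmax(w))
    top = w[peak]
    if top <= 0 or np.all(w == w[0]):
        raise ValueError("IRF is flat or empty: FWHM undefined")
    half = top / 2.0

    def _crossing(idx_range, side) -> float:
        prev = peak
        for i in idx_range:
            if w[i] <= half:
                # linear interpolation between bins i and prev
                frac = (half - w[i]) / (w[prev] - w[i])
                return i + frac * (prev - i)
            prev = i
        # signal never drops below half on this side: clamp at grid edge
        return float(idx_range[-1]) if len(idx_range) else float(peak)

    left = _crossing(range(peak - 1, -1, -1), "left")
    right = _crossing(range(peak + 1, len(w)), "right")
    return float((right - left) * irf.grid.dt)


def convolve_with_irf(
    model: np.ndarray, irf: InstrumentResponse, grid: TimeGrid
) -> np.ndarray:
    """Causal discrete convolution of a model curve with the normalized IRF.

    The IRF weights are a probability mass on the grid (sum 1), so
    ``out[i] = sum_k w[k] * model[i-k]``: a delta IRF is the identity and
    total signal mass is preserved up to truncation at the grid end.  Direct
    summation is used for bit-stable results at these sizes.
    """
    model = np.asarray(model, dtype=float)
    if not grid.compatible_spacing(irf.grid, rtol=1e-6):
        raise ValueError(
            f"IRF grid spacing {irf.grid.dt} != profile spacing {grid.dt}"
        )
    if model.shape != (grid.n_bins,):
        raise ValueError("model length must equal grid n_bins")
    return np.convolve(model, irf.weights)[: grid.n_bins]


def simulate_counts(
    expected: np.ndarray,
    total_counts: float,
    rng_seed: int | np.random.Generator,
) -> np.ndarray:
    """Poisson photon-counting realization of an expected flux shape.

    Rescales ``expected`` to sum to ``total_counts`` and draws independent
    Poisson counts per bin.  Emulates a fixed-duration photon-counting
    acquisition; the same seed reproduces the same counts.
    """
    expected = np.asarray(expected, dtype=float)
    if np.any(expected < 0):
        raise ValueError("expected flux must be nonnegative")
    total = expected.sum()
    if total <= 0:
        raise ValueError("expected flux is all zero")
    if not total_counts > 0:
        raise ValueError("total_counts must be positive")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    lam = expected * (total_counts / total)
    return rng.poisson(lam).astype(float)
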