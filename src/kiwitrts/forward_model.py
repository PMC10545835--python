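"""Time-domain diffusion model of light transmittance through a turbid slab.

A picosecond light pulse injected into a highly scattering, weakly absorbing
medium (fruit flesh at ~850 nm) spreads diffusively.  For a homogeneous slab
of thickness ``s`` the diffusion approximation has a closed-form solution for
the photon flux emerging from the far face: an infinite series of positive
and negative image ("dipole") sources mirrored across extrapolated
boundaries, each contributing a Gaussian-in-depth term, all damped by a
common Beer-Lambert absorption factor ``exp(-mu_a * v * t)``.

Conventions used throughout the package:

* lengths in mm, times in ps, coefficients in mm^-1;
* the diffusion length is absorption-independent, ``D = 1/(3 mu_s')``;
* the isotropic source sits one transport mean free path inside the slab,
  ``z0 = 1/mu_s'``; the extrapolation length is ``ze = 2 A D`` where ``A``
  encodes internal reflection at the boundary;
* the returned flux is the nonnegative magnitude of the dipole sum times
  the common prefactor, and is exactly zero for ``t <= 0``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "C_VACUUM_MM_PER_PS",
    "OpticalProperties",
    "SlabGeometry",
    "DerivedDiffusionQuantities",
    "derived_quantities",
    "image_source_positions",
    "transmittance_curve",
    "mean_time_of_flight",
]

#: Speed of light in vacuum, mm per ps.
C_VACUUM_MM_PER_PS = 0.299792458


@dataclass(frozen=True)
class OpticalProperties:
    """Absorption and reduced scattering coefficients, both in mm^-1.

    ``mu_s_prime = (1 - g) * mu_s`` is the reduced scattering coefficient;
    the anisotropy factor ``g`` never enters the computation.  The diffusion
    approximation assumes scattering dominates absorption, so a pair with
    ``mu_s_prime <= mu_a`` triggers a warning (not an error).
    """

    mu_a: float
    mu_s_prime: float

    def __post_init__(self) -> None:
        if not (self.mu_a > 0 and np.isfinite(self.mu_a)):
            raise ValueError(f"mu_a must be positive and finite, got {self.mu_a}")
        if not (self.mu_s_prime > 0 and np.isfinite(self.mu_s_prime)):
            raise ValueError(
                f"mu_s_prime must be positive and finite, got {self.mu_s_prime}"
            )
        if self.mu_s_prime <= self.mu_a:
            warnings.warn(
                "mu_s_prime <= mu_a: outside the diffusion regime, the slab "
                "solution is unreliable",
                stacklevel=2,
            )


@dataclass(frozen=True)
class SlabGeometry:
    """Slab thickness and boundary parameters of the transmittance geometry.

    ``thickness_s`` is the source-to-detector path, i.e. the fruit diameter;
    ``rho`` is the lateral offset of the detection fiber from the source axis
    (0 in on-axis transmittance); ``boundary_A`` accounts for internal
    reflection at the tissue/air boundary; ``dipole_max_m`` truncates the
    image-source series at ``|m| <= dipole_max_m`` (the default keeps seven
    dipoles, m = 0, +-1, +-2, +-3).
    """

    thickness_s: float
    rho: float = 0.0
    refractive_index_n: float = 1.34
    boundary_A: float = 2.58
    dipole_max_m: int = 3

    def __post_init__(self) -> None:
        if not self.thickness_s > 0:
            raise ValueError("thickness_s must be positive")
        if self.rho < 0:
            raise ValueError("rho must be nonnegative")
        if self.refractive_index_n < 1:
            raise ValueError("refractive_index_n must be >= 1")
        if not self.boundary_A > 0:
            raise ValueError("boundary_A must be positive")
        if not (isinstance(self.dipole_max_m, (int, np.integer)) and self.dipole_max_m >= 0):
            raise ValueError("dipole_max_m must be a nonnegative integer")


@dataclass(frozen=True)
class DerivedDiffusionQuantities:
    """Quantities derived from (mu_a, mu_s', n, A): all positive, mm/ps units."""

    v: float  # light speed in the medium, mm/ps
    D: float  # diffusion length, mm
    z0: float  # isotropic source depth, mm
    ze: float  # extrapolation length, mm


def derived_quantities(
    props: OpticalProperties, geom: SlabGeometry
) -> DerivedDiffusionQuantities:
    """Compute v = c/n, D = 1/(3 mu_s'), z0 = 1/mu_s', ze = 2 A D."""
    v = C_VACUUM_MM_PER_PS / geom.refractive_index_n
    D = 1.0 / (3.0 * props.mu_s_prime)
    z0 = 1.0 / props.mu_s_prime
    ze = 2.0 * geom.boundary_A * D
    return DerivedDiffusionQuantities(v=v, D=D, z0=z0, ze=ze)


def image_source_positions(
    m: int, geom: SlabGeometry, derived: DerivedDiffusionQuantities
) -> tuple[float, float]:
    """Depths (Z1m, Z2m) of the positive and negative image source of order m.

    Z1m = s(1-2m) - 4m ze - z0 and Z2m = s(1-2m) - (4m-2) ze + z0.
    """
    if abs(m) > geom.dipole_max_m:
        raise ValueError(f"|m|={abs(m)} exceeds dipole_max_m={geom.dipole_max_m}")
    s, z0, ze = geom.thickness_s, derived.z0, derived.ze
    z1 = s * (1 - 2 * m) - 4 * m * ze - z0
    z2 = s * (1 - 2 * m) - (4 * m - 2) * ze + z0
    return z1, z2


def _signed_sources(
    props: OpticalProperties, geom: SlabGeometry, derived: DerivedDiffusionQuantities
) -> tuple[np.ndarray, np.ndarray]:
    """Depths and signed weights of all dipole terms with |m| <= dipole_max_m."""
    m = np.arange(-geom.dipole_max_m, geom.dipole_max_m + 1)
    s, z0, ze = geom.thickness_s, derived.z0, derived.ze
    z1 = s * (1 - 2 * m) - 4 * m * ze - z0
    z2 = s * (1 - 2 * m) - (4 * m - 2) * ze + z0
    depths = np.concatenate([z1, z2])
    coeffs = np.concatenate([z1, -z2])
    return depths, coeffs


def transmittance_curve(
    t_grid: np.ndarray, props: OpticalProperties, geom: SlabGeometry
) -> np.ndarray:
    """Photon flux emerging from the far slab face at each time (arbitrary units).

    Evaluates the image-source series truncated at ``|m| <= geom.dipole_max_m``.
    Entries with ``t <= 0`` map to exactly 0 (causality; the ``t^{5/2}`` pole is
    never touched).  To limit cancellation and underflow, the largest dipole
    exponent is factored out of the sum and all scale factors are combined in
    log space before the single final exponential.

    Parameters
    ----------
    t_grid : array of times in ps, sorted ascending.
    props, geom : medium and slab description.

    Returns
    -------
    Nonnegative flux values, one per grid time.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.size == 0:
        raise ValueError("t_grid is empty")
    if np.any(np.diff(t) < 0):
        raise ValueError("t_grid must be sorted ascending")

    d = derived_quantities(props, geom)
    depths, coeffs = _signed_sources(props, geom, d)

    out = np.zeros_like(t)
    pos = t > 0
    if not np.any(pos):
        return out
    tp = t[pos]

    denom = 4.0 * d.D * d.v * tp  # mm^2
    # exponents of each dipole term, shape (n_times, n_terms)
    expo = -(depths[None, :] ** 2) / denom[:, None]
    emax = expo.max(axis=1)
    series = (coeffs[None, :] * np.exp(expo - emax[:, None])).sum(axis=1)

    log_prefactor = (
        -props.mu_a * d.v * tp
        - geom.rho**2 / denom
        - np.log(2.0)
        - 1.5 * np.log(4.0 * np.pi * d.D * d.v)
        - 2.5 * np.log(tp)
    )
    with np.errstate(under="ignore"):
        out[pos] = np.exp(log_prefactor + emax) * np.abs(series)

    if not np.all(np.isfinite(out)):
        raise FloatingPointError("transmittance_curve produced NaN or Inf")
    return out


def mean_time_of_flight(curve: np.ndarray, t_grid: np.ndarray) -> float:
    """Intensity-weighted mean arrival time sum(t*f)/sum(f) on the grid, ps.

    Diagnostic for the scattering-induced delay: larger mu_s' shifts photon
    arrival later at fixed absorption and geometry.
    """
    f = np.asarray(curve, dtype=float)
    t = np.asarray(t_grid, dtype=float)
    if f.shape != t.shape:
        raise ValueError("curve and t_grid must have the same shape")
    if np.any(f < 0):
        raise ValueError("curve must be nonnegative")
    total = f.sum()
    if total <= 0:
        raise ValueError("curve is all zero: mean time of flight undefined")
    return float((t * f).sum() / total)
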