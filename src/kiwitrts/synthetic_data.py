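"""Synthetic kiwifruit storage studies with realistic statistical structure.

Real storage experiments of this kind are rarely deposited, so the
generator emulates one end to end: per-fruit reduced-scattering
trajectories that decay exponentially with storage day toward a floor
(faster under shelf-life than cold storage), roughly day-independent
absorption around 0.01 mm^-1, fruit diameters near 51 mm, firmness tied
affinely to the latent mu_s', weakly day-correlated skin color, and
time-resolved profiles rendered through the slab diffusion model, convolved
with a Gaussian IRF and Poisson-sampled at a fixed total photon count.

Everything is driven by a single seed: the same configuration reproduces
the same study byte for byte.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .forward_model import OpticalProperties, SlabGeometry, transmittance_curve
from .instrument import (
    DEFAULT_GRID,
    InstrumentResponse,
    TimeGrid,
    TimeResolvedProfile,
    convolve_with_irf,
    make_gaussian_irf,
    simulate_counts,
)

__all__ = ["StudyConfig", "StudyDataset", "mu_s_trajectory", "generate_study", "write_fixture"]

MANIFEST_COLUMNS = [
    "sample_id",
    "condition",
    "day",
    "diameter_mm",
    "firmness_N_cm2",
    "ssc_brix",
    "ph",
    "L_star",
    "a_star",
    "b_star",
    "trp_path",
]


@dataclass(frozen=True)
class StudyConfig:
    """Generator settings; the defaults define the reference study conditions.

    Day grids and sample counts mirror a two-arm storage design: ten fruit
    measured on days (0,1,3,5,7,9,11,13) at room temperature ("shelf") and
    ten on days (0,7,...,49) refrigerated ("cold").  Scattering decays with
    time constants of 6 d (shelf) and 30 d (cold) from fruit-specific day-0
    values toward a shared floor, with 10% lognormal measurement jitter.
    Firmness is an affine function of the latent mu_s' spanning roughly
    5-30 N/cm^2; skin color trends are weak relative to their noise.
    """

    n_samples: int = 10
    shelf_days: tuple = (0, 1, 3, 5, 7, 9, 11, 13)
    cold_days: tuple = (0, 7, 14, 21, 28, 35, 42, 49)
    mu_s0_mean: float = 0.75
    mu_s0_sd: float = 0.18
    mu_s0_clip: tuple = (0.45, 1.15)
    mu_s_floor: float = 0.35
    tau_shelf: float = 6.0
    tau_cold: float = 30.0
    measurement_jitter_cv: float = 0.10
    mu_a_mean: float = 0.010
    mu_a_sd: float = 0.003
    mu_a_clip: tuple = (0.003, 0.023)
    diameter_mean: float = 51.0
    diameter_sd: float = 0.8
    firmness_slope: float = 35.0
    firmness_intercept: float = 2.0
    firmness_ref_mu_s: float = 0.2
    firmness_noise_sd: float = 2.0
    # skin color: per-fruit baseline spread, weak per-day linear drift,
    # per-measurement noise large enough that |r(color, day)| stays small
    color_base: tuple = (57.0, 5.5, 20.0)       # L*, a*, b* means
    color_base_sd: tuple = (2.5, 1.5, 2.0)
    color_slope: tuple = (-0.05, 0.02, -0.05)   # per day
    color_noise_sd: float = 1.5
    ssc_mean: float = 13.0
    ssc_sd: float = 1.5
    ssc_slope: float = 0.03
    ph_mean: float = 3.3
    ph_sd: float = 0.15
    ph_slope: float = 0.01
    total_counts: float = 1e6
    irf_fwhm: float = 159.83
    irf_center: float = 200.0
    grid: TimeGrid = DEFAULT_GRID
    seed: int = 0

    def __post_init__(self) -> None:
        positive = {
            "n_samples": self.n_samples,
            "mu_s0_mean": self.mu_s0_mean,
            "mu_s_floor": self.mu_s_floor,
            "tau_shelf": self.tau_shelf,
            "tau_cold": self.tau_cold,
            "mu_a_mean": self.mu_a_mean,
            "diameter_mean": self.diameter_mean,
            "total_counts": self.total_counts,
            "irf_fwhm": self.irf_fwhm,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ValueError(f"StudyConfig.{name} must be positive, got {value}")
        for name, days in (("shelf_days", self.shelf_days), ("cold_days", self.cold_days)):
            if list(days) != sorted(days):
                raise ValueError(f"StudyConfig.{name} must be sorted ascending")
        if not self.mu_s_floor < self.mu_s0_clip[0]:
            raise ValueError("mu_s_floor must lie below the mu_s0 clip range")
        if self.measurement_jitter_cv < 0:
            raise ValueError("measurement_jitter_cv must be nonnegative")


@dataclass
class StudyDataset:
    """A complete simulated study: phenotype records, TRPs, IRF, and the
    latent ground-truth optical properties (synthetic data only)."""

    records: pd.DataFrame
    trps: dict
    irf: InstrumentResponse
    truth: pd.DataFrame
    config: StudyConfig | None = None


def mu_s_trajectory(
    day: float,
    mu_s0: float,
    floor: float,
    tau: float,
    jitter_cv: float,
    rng: np.random.Generator,
) -> float:
    """Latent mu_s' on a given storage day: exponential decay toward a floor.

    ``floor + (mu_s0 - floor) * exp(-day/tau)``, multiplied by unit-mean
    lognormal jitter with the requested coefficient of variation (zero CV
    means no draw, so day 0 returns mu_s0 exactly).
    """
    if not tau > 0:
        raise ValueError("tau must be positive")
    if not 0 < floor < mu_s0:
        raise ValueError("need 0 < floor < mu_s0")
    base = floor + (mu_s0 - floor) * np.exp(-day / tau)
    if jitter_cv == 0:
        return float(base)
    sigma = np.sqrt(np.log1p(jitter_cv**2))
    return float(base * rng.lognormal(-0.5 * sigma**2, sigma))


def _clipped_normal(rng, mean, sd, clip, size=None):
    return np.clip(rng.normal(mean, sd, size), *clip)


def generate_study(config: StudyConfig | None = None) -> StudyDataset:
    """Draw a full two-condition storage study from the generator.

    Per fruit: a day-0 mu_s' and a diameter; per measurement day: a latent
    (mu_a, mu_s'), a TRP rendered as slab model (s = diameter) x IRF scaled
    to the configured total counts and Poisson-sampled, plus firmness,
    SSC, pH, and CIELAB color draws.  Every TRP carries the same expected
    total count, so storage-induced change shows up as a reshaping of the
    profile (earlier, taller peak), not as a change in total intensity.
    """
    config = config or StudyConfig()
    rng = np.random.default_rng(config.seed)
    irf = make_gaussian_irf(config.grid, config.irf_fwhm, config.irf_center)
    times = config.grid.times

    records = []
    truth_rows = []
    trps = {}
    for condition, days, tau in (
        ("shelf", config.shelf_days, config.tau_shelf),
        ("cold", config.cold_days, config.tau_cold),
    ):
        for i in range(1, config.n_samples + 1):
            sid = f"{condition}-{i:02d}"
            mu_s0 = float(_clipped_normal(rng, config.mu_s0_mean, config.mu_s0_sd, config.mu_s0_clip))
            diameter = float(rng.normal(config.diameter_mean, config.diameter_sd))
            geom = SlabGeometry(thickness_s=diameter)
            base_color = [
                rng.normal(m, s) for m, s in zip(config.color_base, config.color_base_sd)
            ]
            ssc0 = rng.normal(config.ssc_mean, config.ssc_sd)
            ph0 = rng.normal(config.ph_mean, config.ph_sd)
            for day in days:
                mu_s = mu_s_trajectory(
                    day, mu_s0, config.mu_s_floor, tau,
                    config.measurement_jitter_cv, rng,
                )
                mu_a = float(_clipped_normal(rng, config.mu_a_mean, config.mu_a_sd, config.mu_a_clip))
                curve = transmittance_curve(times, OpticalProperties(mu_a, mu_s), geom)
                expected = convolve_with_irf(curve, irf, config.grid)
                counts = simulate_counts(expected, config.total_counts, rng)
                meta = {"sample_id": sid, "condition": condition, "day": day}
                trps[(sid, day)] = TimeResolvedProfile(config.grid, counts, meta)

                firmness = max(
                    0.5,
                    config.firmness_intercept
                    + config.firmness_slope * (mu_s - config.firmness_ref_mu_s)
                    + rng.normal(0.0, config.firmness_noise_sd),
                )
                color = [
                    b + s * day + rng.normal(0.0, config.color_noise_sd)
                    for b, s in zip(base_color, config.color_slope)
                ]
                records.append(
                    {
                        "sample_id": sid,
                        "condition": condition,
                        "day": day,
                        "diameter_mm": round(diameter, 2),
                        "firmness_N_cm2": firmness,
                        "ssc_brix": ssc0 + config.ssc_slope * day + rng.normal(0, 0.3),
                        "ph": ph0 + config.ph_slope * day + rng.normal(0, 0.05),
                        "L_star": color[0],
                        "a_star": color[1],
                        "b_star": color[2],
                        "trp_path": f"trp/{sid}_{day:02d}.csv",
                    }
                )
                truth_rows.append(
                    {
                        "sample_id": sid,
                        "condition": condition,
                        "day": day,
                        "mu_a": mu_a,
                        "mu_s_prime": mu_s,
                    }
                )

    return StudyDataset(
        records=pd.DataFrame(records),
        trps=trps,
        irf=irf,
        truth=pd.DataFrame(truth_rows),
        config=config,
    )


def write_fixture(
    study: StudyDataset,
    directory: str,
    export_truth: bool = True,
    overwrite: bool = False,
) -> str:
    """Write a study to disk as plain CSVs; returns the manifest path.

    Layout: ``manifest.csv``, ``irf.csv``, optionally ``truth.csv``, and one
    two-column ``trp/<sample>_<day>.csv`` per profile.  Refuses to write
    into a non-empty directory unless ``overwrite`` is set.
    """
    os.makedirs(directory, exist_ok=True)
    if os.listdir(directory) and not overwrite:
        raise FileExistsError(f"{directory} is not empty (pass overwrite=True)")
    os.makedirs(os.path.join(directory, "trp"), exist_ok=True)

    times = study.irf.grid.times
    pd.DataFrame({"time_ps": times, "counts": study.irf.weights}).to_csv(
        os.path.join(directory, "irf.csv"), index=False
    )
    for (sid, day), trp in study.trps.items():
        pd.DataFrame({"time_ps": trp.grid.times, "counts": trp.counts}).to_csv(
            os.path.join(directory, "trp", f"{sid}_{day:02d}.csv"), index=False
        )
    manifest_path = os.path.join(directory, "manifest.csv")
    study.records[MANIFEST_COLUMNS].to_csv(manifest_path, index=False)
    if export_truth:
        study.truth.to_csv(os.path.join(directory, "truth.csv"), index=False)
    return manifest_path
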