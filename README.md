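# kiwitrts

Time-resolved transmittance spectroscopy (TRTS) analysis of fruit softening,
built around the 'Hayward' kiwifruit storage problem: a picosecond laser
pulse is injected through the equator of an intact fruit, a streak camera
histograms the arrival times of transmitted photons (a *time-resolved
profile*, TRP), and the shape of that histogram separates light scattering
from light absorption.  Because the reduced scattering coefficient μs′ of
fruit flesh tracks the mechanical breakdown of cell walls, its decline over
storage days is a non-destructive window onto softening that skin color
cannot provide — kiwifruit skin barely changes as the fruit ripens.

The package is aimed at researchers in biophotonics and postharvest
physiology who want a tested, reusable implementation of the full analysis
chain rather than a one-off script.

## What it computes

**Forward model.**  The diffusion approximation for a homogeneous slab of
thickness *s* (the fruit diameter) gives the transmitted photon flux as an
image-source ("dipole") series over extrapolated boundaries:

```
T(ρ,t) = exp(−μa v t − ρ²/4Dvt) / (2 (4πDv)^{3/2} t^{5/2})
         · | Σ_m  Z₁,ₘ exp(−Z₁,ₘ²/4Dvt) − Z₂,ₘ exp(−Z₂,ₘ²/4Dvt) |

Z₁,ₘ = s(1−2m) − 4m zₑ − z₀        z₀ = 1/μs′
Z₂,ₘ = s(1−2m) − (4m−2) zₑ + z₀    zₑ = 2AD,  D = 1/(3 μs′),  v = c/n
```

truncated at |m| ≤ 3 (seven dipoles) by default, with A = 2.58 and
n = 1.34 for fruit tissue.  Units are mm, ps, mm⁻¹ throughout.

**Inverse fit.**  A measured TRP is modeled as `amplitude · (T ⊗ IRF)`,
where the instrument response function is measured (or a Gaussian stand-in
with FWHM 159.83 ps), and (μa, μs′, amplitude) are estimated by
trust-region-reflective least squares within μs′ ∈ [0.1, 10] mm⁻¹ and
μa ∈ [0.0001, 0.1] mm⁻¹.

**Staging analysis.**  Savitzky–Golay smoothing (order 2, frame 5), day-0
difference spectra per fruit, PCA, firmness-based tertile labels
(class 1 = firmest), and a five-fold cross-validated linear SVM give a
three-class early/mid/late softening classification.  Per-fruit Pearson
correlations of μs′, μa, and six CIELAB color indices against storage day
quantify which signals actually track softening.

**Synthetic studies.**  A seeded generator renders complete two-arm storage
studies (shelf-life vs cold) — latent μs′ trajectories, Poisson-noise TRPs
through the forward model, firmness, color, SSC, pH — so the whole pipeline
is testable end to end without access to instrument data.

## Worked example

```python
import numpy as np
from kiwitrts import (
    OpticalProperties, SlabGeometry, transmittance_curve, make_gaussian_irf,
    convolve_with_irf, simulate_counts, fit_optical_properties,
    TimeResolvedProfile, DEFAULT_GRID, correlate_with_time,
)
from kiwitrts.datasets import shelf_life_table, SHELF_LIFE_DAYS

# 1. published worked example: how strongly does scattering track storage?
mu_s = shelf_life_table()["mu_s_prime"].loc[1].to_numpy()
r = correlate_with_time(np.array(SHELF_LIFE_DAYS, float), mu_s)
print(f"fruit 1, shelf-life: r(mu_s', day) = {r:.2f}")

# 2. simulate one measurement and invert it
grid = DEFAULT_GRID                       # 486 bins of 10.3 ps (~5 ns)
irf = make_gaussian_irf(grid, fwhm=159.83, center=200.0)
truth = OpticalProperties(mu_a=0.010, mu_s_prime=0.60)
geom = SlabGeometry(thickness_s=51.0)     # fruit diameter in mm
model = convolve_with_irf(transmittance_curve(grid.times, truth, geom), irf, grid)
counts = simulate_counts(model, total_counts=1e6, rng_seed=0)
fit = fit_optical_properties(TimeResolvedProfile(grid, counts), irf, geom)
print(f"fitted mu_a = {fit.props.mu_a:.4f} mm^-1, "
      f"mu_s' = {fit.props.mu_s_prime:.3f} mm^-1 (truth 0.010, 0.600)")
```

prints

```
fruit 1, shelf-life: r(mu_s', day) = -0.74
fitted mu_a = 0.0100 mm^-1, mu_s' = 0.600 mm^-1 (truth 0.010, 0.600)
```

The r = −0.74 is the per-fruit correlation between storage day and the
tabulated μs′ trajectory of the first shelf-life fruit: scattering falls
steadily as the fruit softens.  The inverse fit recovers the optical
properties used to render the simulated histogram to within the Poisson
noise floor (~0.1% here at 10⁶ counts).

## Command line

```bash
kiwitrts simulate --out study/                 # write a synthetic fixture
kiwitrts fit --manifest study/manifest.csv --irf study/irf.csv --out fits.csv
kiwitrts analyze --manifest study/manifest.csv --fits fits.csv --out analysis/
kiwitrts classify --manifest study/manifest.csv --out analysis/ --seed 1
kiwitrts run --out bundle/ --seed 1            # all of the above in one go
```

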