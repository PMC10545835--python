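# Methods

## The measurement and the model

Time-resolved transmittance spectroscopy injects a picosecond light pulse
into one side of a turbid sample and histograms the arrival times of the
photons that emerge from the other side.  In the 800–900 nm window, fruit
flesh scatters light far more strongly than it absorbs it
(μs′ ≈ 0.25–1.2 mm⁻¹ versus μa ≈ 0.003–0.05 mm⁻¹), so photon transport
through a ~50 mm fruit is well inside the diffusion regime and the
transmitted pulse is delayed and broadened to the nanosecond scale.

We model the fruit as a homogeneous slab of thickness *s* (the measured
diameter) and use the diffusion-approximation transmittance with
extrapolated-boundary image sources.  Each reflection order *m*
contributes a positive source at depth `Z1,m = s(1−2m) − 4m·ze − z0` and a
negative one at `Z2,m = s(1−2m) − (4m−2)·ze + z0`, where `z0 = 1/μs′` is
the depth of the equivalent isotropic source, `ze = 2AD` the extrapolation
length, and `D = 1/(3 μs′)` the diffusion length.  Absorption enters only
through the common factor `exp(−μa v t)` with `v = c/n`; this exact
factorization is one of the model's sharpest internal tests and is
asserted to 1e−12 in the suite.

Conventions and numerical choices:

* **Units** are fixed internally: mm, ps, mm⁻¹; `c = 0.299792458 mm/ps` is
  a named constant.
* **Sign.**  Some presentations of the slab solution carry a leading minus
  while the m = 0 bracket is positive for this geometry; we define the
  output as the nonnegative magnitude of the dipole sum times the (positive)
  prefactor, and tests assert nonnegativity everywhere.
* **Diffusion length** excludes absorption (`D = 1/(3μs′)`, not
  `1/(3(μa+μs′))`), the convention consistent with `z0 = 1/μs′` and with
  absorption factoring out exactly.
* **Truncation** at |m| ≤ 3 (seven dipoles).  For s ∈ [40, 60] mm and the
  optical ranges above, the |m| ≤ 3 series agrees with |m| ≤ 25 to better
  than 1e−4 everywhere on 50–5000 ps and to 1e−8 at the peak; the test
  suite also checks double precision against an arbitrary-precision
  evaluation of the series (mpmath, 50 digits, |m| ≤ 50) to 1e−10.
* **Stability.**  The largest dipole exponent is factored out of the sum
  and all scale factors are combined in log space before a single final
  exponential, limiting cancellation and underflow at early times.
* **Causality.**  t ≤ 0 maps to exactly zero; the t^{5/2} pole is never
  evaluated.

## Instrument response and convolution

What the streak camera records is the slab response convolved with the
instrument response function.  The default analysis grid is 486 bins of
10.3 ps (≈5 ns), matching a typical streak-camera configuration; the IRF
may be read from a two-column CSV or generated as a discretized Gaussian
(default FWHM 159.83 ps).  IRF weights are stored normalized to unit sum
and treated as a probability mass on the grid, so the causal discrete
convolution `out[i] = Σ_k w[k]·f[i−k]` has the delta IRF as its identity
and preserves total signal mass up to truncation at the grid end
(equivalently: w/dt is the sampled IRF density and the convolution
integral is multiplied by dt).  Direct summation is used rather than FFTs
— at ~500 bins it is effectively free and bit-stable.

Photon counting is emulated as independent Poisson draws per bin after
rescaling the expected curve to a target total (default 10⁶ counts,
representative of a ~60 s acquisition).

## Inverse estimation

A measured TRP is fitted as `amplitude · (model ⊗ IRF)` over the entire
grid by box-constrained trust-region-reflective least squares
(`scipy.optimize.least_squares`).  Default bounds are μs′ ∈ [0.1, 10] mm⁻¹
and μa ∈ [0.0001, 0.1] mm⁻¹; the start is (μs′, μa) = (1.0, 0.01), the
geometric midpoints, with the amplitude started from total-count matching.
The free multiplicative amplitude absorbs the unknown conversion between
model flux units and recorded counts; an optional time-shift parameter
(default off) can absorb IRF/TRP trigger misalignment.  The loss is
unweighted least squares on counts (a Poisson-weighted variant is
available by flag).  Convergence uses relative tolerance 1e−8 on
parameters and cost with a 1000-evaluation budget; exhausting the budget
is reported as `converged=False`, and estimates within 1e−6 of a bound
(relative to its width) are flagged in `at_bound` so low-quality fits can
be filtered rather than silently trusted.

Self-consistency: noiseless round trips recover μs′ and μa to machine
precision across the physiological grid; at 10⁶ Poisson counts the median
relative μs′ error is ~0.1%, far inside the 5% acceptance envelope.

## Preprocessing and staging

TRPs are smoothed with a Savitzky–Golay filter (order 2, frame 5 — interior
weights (−3, 12, 17, 12, −3)/35), the standard light-touch smoother for
photon-counting histograms; smoothing is applied at ingest for the PCA
path and is optional (default off) before inverse fitting, since the fit
already averages over the full grid.  Filter output is clamped at zero so
a smoothed TRP remains a valid count histogram.  A constant dark-count
floor can be removed from a pre-pulse window, clamped at zero.

Per-fruit day-0 difference spectra (day d minus day 0) remove initial
quality variation; they are kept in absolute counts (no per-curve area
normalization by default).  PCA is column-mean-centered with no variance
scaling — all bins share count units — and component signs are fixed so
each loading's largest-magnitude element is positive, making loadings and
scores reproducible across runs.

Softening classes are equal-count tertiles of firmness rank (class 1 =
firmest), with ties broken by stable input order; no firmness cut values
are assumed a priori, and the realized cuts are reported.  Three
components are selected among the first ten by the ratio of between-class
to within-class score variance (an explicit index list overrides the
rule; degenerate within-class variance falls back to variance ordering
with a warning).  Classification is a linear-kernel SVM (C = 1, one-vs-one
multiclass) with features standardized inside each training fold,
evaluated by stratified five-fold cross-validation; accuracy is the pooled
out-of-fold trace/total of a single confusion matrix (rows = predicted,
columns = actual), which matches how a single printed confusion matrix is
normally summarized.

Color indices use the single-argument ratio conventions
Chroma = √(a*² + b*²) and Hue = arctan(b*/a*) in degrees.  The ratio form
of hue folds quadrants — a fruit with a* < 0 maps onto the mirrored
angle — which is accepted deliberately for comparability with common
colorimeter practice; hue is undefined at a* = 0 and reported as absent.
Correlations are Pearson product-moment r per fruit against storage day;
degenerate cells (fewer than 3 finite pairs, zero variance) are reported
as missing, never as 0.

## The synthetic study generator

No public dataset pairs raw TRPs with storage phenotypes, so the generator
emulates a two-arm storage study with the statistical structure the
analysis assumes.  Defaults (all configurable, one seed drives
everything):

| quantity | default | rationale |
|---|---|---|
| fruit per arm | 10 | typical tracked-sample cohort |
| shelf-life days | 0,1,3,5,7,9,11,13 | room-temperature measurement grid |
| cold-storage days | 0,7,…,49 | weekly refrigerated grid |
| day-0 μs′ | N(0.75, 0.18²) clipped to [0.45, 1.15] mm⁻¹ | observed day-0 spread |
| μs′ decay | floor 0.35 + exp decay, τ = 6 d (shelf) / 30 d (cold) | softening faster at room temperature |
| measurement jitter | 10% lognormal CV | fit-to-fit variability |
| μa | N(0.010, 0.003²) clipped to [0.003, 0.023] mm⁻¹, i.i.d. per day | absorption carries no storage signal |
| diameter | N(51, 0.8²) mm | ~50–52 mm fruit |
| firmness | 2 + 35·(μs′ − 0.2) + N(0, 2) N/cm² | affine link spanning ≈5–30 N/cm² |
| skin color | weak linear drifts + sd 1.5 noise | color barely tracks storage |
| TRP counts | 10⁶ total per profile, Poisson | 60 s photon counting |
| IRF | Gaussian, FWHM 159.83 ps, centered 200 ps | measured system response scale |

Each TRP is rendered through the forward model at the fruit's diameter,
convolved with the IRF, rescaled to the fixed total count, and
Poisson-sampled.  Because every profile carries the same expected total,
storage-induced change appears as a reshaping (earlier, taller peak), not
as a change in total intensity; real fixed-duration acquisitions would
also show an absolute intensity rise, so synthetic staging accuracy
should be read as a conservative emulation in that respect.  The
firmness–μs′ link is a declared modeling choice for testability — the
field documents a positive association but no quantitative law.

What passing the end-to-end tests shows: the pipeline recovers the latent
μs′ trajectories (median error ≪ 5%), reproduces the strong negative
per-fruit r(μs′, day) with the shelf/cold contrast in expectation, and
stages softening well above chance.  What it does not show: performance on
real fruit, where heterogeneity (core vs flesh, skin), non-exponential
softening kinetics, detector artifacts, and day-to-day instrument drift
all lie outside the generator.

A note on the staging ceiling: with the default firmness noise (sd
2 N/cm²), tertile labels near the class cuts are intrinsically ambiguous —
even a classifier given the exact latent μs′ averages only ≈0.79 pooled
accuracy on the shelf arm, and PCA-score features reach ≈0.6–0.8
depending on the seed.  Reported staging accuracies should be interpreted
against that ceiling.

## Pipeline and reproducibility

`run_pipeline` (or the `kiwitrts` CLI) executes simulate/load → fit →
correlate → stage from a single declarative config; unknown config keys
are rejected by name.  One top-level seed is split deterministically per
stage (study generation uses the seed, cross-validation seed + 1), reruns
are byte-identical, and every bundle includes a run log with package
versions, the seed, and a config hash.  CSV outputs use 6 significant
digits except correlation tables, which use 2 decimals to match how such
tables are conventionally presented.

## Known limitations

* Homogeneous-slab forward model: no layered skin/flesh/core structure,
  no reflectance geometry, no Monte Carlo cross-check.
* Single wavelength; no spectral fitting.
* The amplitude/time-zero conventions of published fitted tables are not
  uniquely identifiable from printed values; this implementation fits a
  free amplitude and (optionally) a time shift and reports both.
* Hue's ratio convention misorders quadrants for a* < 0.
* No uncertainty quantification beyond residual and bound diagnostics.
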