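import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kiwitrts.instrument import (
    InstrumentResponse,
    TimeGrid,
    TimeResolvedProfile,
    convolve_with_irf,
    estimate_fwhm,
    make_gaussian_irf,
    simulate_counts,
)

from _oracles import emg_curve


def delta_irf(grid, at_bin=0):
    w = np.zeros(grid.n_bins)
    w[at_bin] = 1.0
    return InstrumentResponse(grid, w)


class TestTimeGridAndTypes:
    def test_uniform_times(self):
        g = TimeGrid(t0=5.0, dt=2.0, n_bins=10)
        np.testing.assert_allclose(g.times, 5.0 + 2.0 * np.arange(10))

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            TimeGrid(dt=-1.0)
        with pytest.raises(ValueError):
            TimeGrid(n_bins=4)

    def test_profile_validation(self, grid):
        with pytest.raises(ValueError):
            TimeResolvedProfile(grid, -np.ones(grid.n_bins))
        with pytest.raises(ValueError):
            TimeResolvedProfile(grid, np.ones(3))


class TestGaussianIrf:
    def test_fwhm_round_trip(self, grid):
        irf = make_gaussian_irf(grid, fwhm=159.83, center=1000.0)
        assert estimate_fwhm(irf) == pytest.approx(159.83, abs=grid.dt)

    def test_unit_mass(self, grid):
        irf = make_gaussian_irf(grid, fwhm=300.0, center=500.0)
        assert irf.weights.sum() == pytest.approx(1.0, rel=1e-12)

    def test_narrow_limit_is_delta(self, grid):
        with pytest.warns(UserWarning, match="under-resolved"):
            irf = make_gaussian_irf(grid, fwhm=1e-3, center=grid.times[30])
        assert irf.weights[30] == pytest.approx(1.0)

    def test_center_outside_span_rejected(self, grid):
        with pytest.raises(ValueError):
            make_gaussian_irf(grid, fwhm=100.0, center=-1000.0)


class TestEstimateFwhm:
    def test_gaussian_closed_form(self, grid):
        sigma = 67.87
        irf = make_gaussian_irf(
            grid, fwhm=2 * np.sqrt(2 * np.log(2)) * sigma, center=1000.0
        )
        # linear interpolation at half height carries a small O(dt^2) bias
        assert estimate_fwhm(irf) == pytest.approx(159.83, abs=0.5)

    def test_rectangular_pulse_width(self, grid):
        w = np.zeros(grid.n_bins)
        w[40:60] = 1.0
        # flat top of k bins has half-crossings half a bin outside each edge
        assert estimate_fwhm(InstrumentResponse(grid, w)) == pytest.approx(
            20 * grid.dt, abs=grid.dt
        )

    def test_scale_invariance(self, grid):
        w = np.exp(-0.5 * ((grid.times - 800.0) / 50.0) ** 2)
        a = estimate_fwhm(InstrumentResponse(grid, w))
        b = estimate_fwhm(InstrumentResponse(grid, 7.5 * w))
        assert a == b

    def test_flat_rejected(self, grid):
        with pytest.raises(ValueError):
            estimate_fwhm(InstrumentResponse(grid, np.ones(grid.n_bins)))


class TestConvolution:
    def test_delta_is_identity(self, grid):
        x = np.exp(-grid.times / 700.0)
        np.testing.assert_array_equal(convolve_with_irf(x, delta_irf(grid), grid), x)

    def test_delta_shift(self, grid):
        x = np.exp(-grid.times / 700.0)
        out = convolve_with_irf(x, delta_irf(grid, at_bin=7), grid)
        np.testing.assert_allclose(out[7:], x[:-7])
        assert np.all(out[:7] == 0)

    def test_grid_mismatch_rejected(self, grid):
        other = TimeGrid(dt=5.0, n_bins=grid.n_bins)
        irf = make_gaussian_irf(other, fwhm=100.0, center=200.0)
        with pytest.raises(ValueError):
            convolve_with_irf(np.ones(grid.n_bins), irf, grid)

    def test_gaussian_exponential_matches_emg(self, grid):
        """Discrete Gaussian (x) exponential decay equals the closed-form
        exponentially-modified Gaussian on interior bins."""
        lam, mu, sigma = 1.0 / 300.0, 500.0, 67.87
        irf = make_gaussian_irf(grid, fwhm=2 * np.sqrt(2 * np.log(2)) * sigma, center=mu)
        x = np.exp(-lam * grid.times)
        out = convolve_with_irf(x, irf, grid)
        ref = emg_curve(grid.times, lam, mu, sigma)
        sel = (grid.times > 1200) & (grid.times < 3500)
        np.testing.assert_allclose(out[sel], ref[sel], rtol=1e-6)

    @given(
        seed=st.integers(0, 2**16),
        shift=st.integers(0, 20),
        a=st.floats(0.1, 5.0),
        b=st.floats(0.1, 5.0),
    )
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_linear_and_translation_equivariant(self, seed, shift, a, b):
        grid = TimeGrid(dt=10.3, n_bins=64)
        rng = np.random.default_rng(seed)
        irf = InstrumentResponse(grid, rng.random(64))
        x, y = rng.random(64), rng.random(64)
        conv = lambda z: convolve_with_irf(z, irf, grid)
        np.testing.assert_allclose(conv(a * x + b * y), a * conv(x) + b * conv(y),
                                   rtol=1e-10, atol=1e-12)
        shifted = np.zeros(64)
        shifted[shift:] = x[: 64 - shift]
        np.testing.assert_allclose(conv(shifted)[shift:], conv(x)[: 64 - shift],
                                   rtol=1e-10, atol=1e-12)

    def test_mass_preserved_for_decayed_signal(self, grid, irf):
        x = np.exp(-((grid.times - 800) / 150.0) ** 2)
        out = convolve_with_irf(x, irf, grid)
        assert out.sum() == pytest.approx(x.sum(), rel=1e-3)


class TestSimulateCounts:
    def test_zero_bins_stay_zero_and_determinism(self):
        expected = np.array([0.0, 1.0, 5.0, 0.0, 3.0])
        a = simulate_counts(expected, 1000, rng_seed=42)
        b = simulate_counts(expected, 1000, rng_seed=42)
        np.testing.assert_array_equal(a, b)
        assert a[0] == 0 and a[3] == 0

    def test_invalid_totals_rejected(self):
        with pytest.raises(ValueError):
            simulate_counts(np.ones(4), 0.0, 1)
        with pytest.raises(ValueError):
            simulate_counts(np.zeros(4), 10.0, 1)

    def test_total_count_statistics(self):
        """Realized totals stay within 3*sqrt(N) of N in >= 95% of replicates."""
        expected = np.exp(-np.arange(100) / 20.0)
        rng = np.random.default_rng(123)
        hits = 0
        for _ in range(200):
            counts = simulate_counts(expected, 1e6, rng)
            hits += abs(counts.sum() - 1e6) <= 3 * np.sqrt(1e6)
        assert hits >= 190
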