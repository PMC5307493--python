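"""Spectra, density estimation, KL divergence and the Δ statistic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.special import rel_entr

from anogva import (DensityEstimationConfig, Graph, GraphPopulation,
                    SpectralDensity, Spectrum, bandwidth, compute_spectrum,
                    delta_statistic, erdos_renyi, estimate_density,
                    kl_divergence, make_grid, population_density,
                    reference_density, sturges_bins)
from anogva.spectral import graph_densities


def _complete(n):
    a = np.ones((n, n)) - np.eye(n)
    return Graph(a)


def _cycle(n):
    a = np.zeros((n, n))
    for i in range(n):
        a[i, (i + 1) % n] = a[(i + 1) % n, i] = 1
    return Graph(a)


def _gaussian_density(grid, mu, sigma=1.0):
    v = np.exp(-0.5 * ((grid - mu) / sigma) ** 2)
    return SpectralDensity(grid, v / np.trapezoid(v, grid))


class TestSpectrum:
    def test_empty_graph_spectrum(self):
        s = compute_spectrum(Graph(np.zeros((4, 4))))
        assert np.array_equal(s.eigenvalues, np.zeros(4))

    def test_complete_graph_closed_form(self):
        # K_n spectrum: n-1 once, -1 with multiplicity n-1
        s = compute_spectrum(_complete(3))
        assert s.eigenvalues == pytest.approx([2, -1, -1], abs=1e-10)
        s5 = compute_spectrum(_complete(5))
        assert s5.eigenvalues == pytest.approx([4, -1, -1, -1, -1], abs=1e-10)

    def test_cycle_closed_form(self):
        # C_n spectrum: 2 cos(2 pi k / n)
        s = compute_spectrum(_cycle(4))
        assert s.eigenvalues == pytest.approx([2, 0, 0, -2], abs=1e-10)

    @pytest.mark.parametrize("mode,scale", [("n", 5), ("sqrt_n", math.sqrt(5))])
    def test_scale_modes_divide_eigenvalues(self, mode, scale):
        g = _complete(5)
        plain = compute_spectrum(g, "none").eigenvalues
        scaled = compute_spectrum(g, mode).eigenvalues
        assert scaled == pytest.approx(plain / scale, abs=1e-12)


class TestSturgesAndBandwidth:
    @pytest.mark.parametrize("count,bins", [(300, 10), (1, 1), (1024, 11),
                                            (4, 3), (100, 8)])
    def test_sturges_rule(self, count, bins):
        assert sturges_bins(count) == bins

    def test_sturges_domain(self):
        with pytest.raises(ValueError):
            sturges_bins(0)

    def test_bandwidth_formula(self):
        # range 4 over ceil(log2(4)+1)=3 bins
        assert bandwidth(Spectrum(np.array([2, 0, 0, -2.]))) == pytest.approx(4 / 3)

    def test_bandwidth_composition_with_sturges(self):
        ev = np.linspace(-3, 7, 300)      # spread R=10 over 10 bins
        assert bandwidth(Spectrum(ev)) == pytest.approx(1.0)

    def test_degenerate_spread_fallback(self):
        h = bandwidth(Spectrum(np.zeros(5)))
        assert h == pytest.approx(1e-3)
        h2 = bandwidth(Spectrum(np.full(5, 7.0)))
        assert h2 == pytest.approx(7e-3)


class TestDensityEstimation:
    def test_unit_integral_enforced(self, rng):
        s = Spectrum(rng.normal(size=60))
        grid = make_grid([s])
        d = estimate_density(s, grid)
        assert d.integral() == pytest.approx(1.0, abs=1e-9)

    def test_repeated_eigenvalue_gives_single_bump(self):
        s = Spectrum(np.full(8, 1.5))
        grid = np.linspace(-1, 4, 400)
        d = estimate_density(s, grid)
        mode = grid[np.argmax(d.values)]
        assert mode == pytest.approx(1.5, abs=grid[1] - grid[0])

    def test_kernel_consistency_against_normal_pdf(self):
        # dense standard-normal pseudo-eigenvalues: the kernel estimate must
        # approach the closed-form pdf in sup distance
        rng = np.random.default_rng(77)
        s = Spectrum(rng.standard_normal(10_000))
        grid = np.linspace(-6, 6, 600)
        d = estimate_density(s, grid, bw=0.12)
        pdf = np.exp(-grid ** 2 / 2) / math.sqrt(2 * math.pi)
        assert np.max(np.abs(d.values - pdf)) < 0.02

    def test_grid_must_cover_eigenvalues(self):
        s = Spectrum(np.array([0.0, 5.0]))
        with pytest.raises(ValueError):
            estimate_density(s, np.linspace(-1, 1, 64))


class TestPopulationAndReference:
    def test_identical_graphs_average_to_single_density(self):
        g = erdos_renyi(20, 0.3, rng=3)
        pop = GraphPopulation("g", [g, g, g])
        spectra = [compute_spectrum(x) for x in pop.graphs]
        grid = make_grid(spectra)
        avg = population_density(pop, grid)
        single = estimate_density(spectra[0], grid)
        assert avg.values == pytest.approx(single.values, abs=1e-12)
        assert avg.integral() == pytest.approx(1.0, abs=1e-9)

    def test_two_graph_average_elementwise(self, rng):
        graphs = [erdos_renyi(15, 0.4, rng) for _ in range(2)]
        grid, rows = graph_densities(graphs)
        pop = GraphPopulation("g", graphs)
        avg = population_density(pop, grid)
        assert avg.values == pytest.approx((rows[0] + rows[1]) / 2, abs=1e-12)

    def test_reference_is_pointwise_mean_and_bounds_support(self):
        grid = np.linspace(-5, 5, 300)
        f = _gaussian_density(grid, -1)
        g = _gaussian_density(grid, 1)
        ref = reference_density([f, g])
        assert ref.values == pytest.approx((f.values + g.values) / 2, abs=1e-14)
        pos = f.values > 0
        assert np.all(ref.values[pos] >= f.values[pos] / 2 - 1e-15)

    def test_identical_densities_reference(self):
        grid = np.linspace(-3, 3, 200)
        f = _gaussian_density(grid, 0)
        ref = reference_density([f, f, f])
        assert ref.values == pytest.approx(f.values, abs=1e-14)

    def test_grid_mismatch_fails_loudly(self):
        f = _gaussian_density(np.linspace(-5, 5, 100), 0)
        g = _gaussian_density(np.linspace(-5, 5, 101), 0)
        with pytest.raises(ValueError, match="grid"):
            kl_divergence(f, g)
        with pytest.raises(ValueError, match="grid"):
            reference_density([f, g])


class TestKLDivergence:
    def test_self_divergence_zero(self):
        f = _gaussian_density(np.linspace(-4, 4, 256), 0)
        assert kl_divergence(f, f) == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_closed_form(self):
        # KL(N(0,1) || N(1,1)) = (mu1-mu2)^2 / 2 = 0.5.  The grid stops
        # where both densities still exceed the numerical mass floor; the
        # truncated tail contributes < 1e-7 to the integral.
        grid = np.linspace(-6, 7, 4000)
        f = _gaussian_density(grid, 0)
        g = _gaussian_density(grid, 1)
        assert kl_divergence(f, g) == pytest.approx(0.5, abs=1e-3)

    def test_infinite_when_support_not_contained(self):
        grid = np.linspace(0, 1, 100)
        left = np.where(grid < 0.5, 1.0, 0.0)
        right = np.where(grid >= 0.5, 1.0, 0.0)
        p = SpectralDensity(grid, left / np.trapezoid(left, grid))
        q = SpectralDensity(grid, right / np.trapezoid(right, grid))
        assert kl_divergence(p, q) == math.inf

    def test_agrees_with_fine_rectangle_rule_oracle(self):
        grid = np.linspace(-8, 9, 6000)
        f = _gaussian_density(grid, 0)
        g = _gaussian_density(grid, 0.7, sigma=1.3)
        step = grid[1] - grid[0]
        oracle = float(np.sum(rel_entr(f.values, g.values)) * step)
        assert kl_divergence(f, g) == pytest.approx(oracle, abs=1e-4)


class TestDeltaStatistic:
    def test_zero_for_identical_densities(self):
        f = _gaussian_density(np.linspace(-4, 4, 128), 0)
        assert delta_statistic([f, f, f]) == pytest.approx(0.0, abs=1e-12)

    def test_two_groups_equals_twice_jensen_shannon(self):
        # independent JSD oracle: trapezoid of rel_entr to the midpoint
        grid = np.linspace(-6, 7, 2048)
        f = _gaussian_density(grid, 0)
        g = _gaussian_density(grid, 1.2)
        m = (f.values + g.values) / 2
        jsd = 0.5 * (np.trapezoid(rel_entr(f.values, m), grid)
                     + np.trapezoid(rel_entr(g.values, m), grid))
        assert delta_statistic([f, g]) == pytest.approx(2 * jsd, rel=1e-10)

    @pytest.mark.parametrize("mus", [(-1, 0, 1), (0, 0.1, 3), (2, 2, 2)])
    def test_nonnegative(self, mus):
        grid = np.linspace(-8, 8, 512)
        ds = [_gaussian_density(grid, m) for m in mus]
        assert delta_statistic(ds) >= 0

    def test_requires_two_densities(self):
        f = _gaussian_density(np.linspace(-4, 4, 64), 0)
        with pytest.raises(ValueError):
            delta_statistic([f])


class TestDensityProperties:
    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(arrays(float, st.integers(3, 40),
                  elements=st.floats(-50, 50, allow_nan=False)))
    def test_any_spectrum_yields_proper_density_with_zero_self_divergence(
            self, eigenvalues):
        s = Spectrum(eigenvalues)
        grid = make_grid([s])
        d = estimate_density(s, grid)
        assert np.all(d.values >= 0)
        assert d.integral() == pytest.approx(1.0, abs=1e-9)
        assert kl_divergence(d, d) == pytest.approx(0.0, abs=1e-12)


class TestAffineInvariance:
    def test_delta_invariant_under_common_rescaling(self, rng):
        # scaling every adjacency by c scales all eigenvalues, bandwidths
        # and the grid together; the KL integrand is scale-free
        graphs = [erdos_renyi(25, 0.3, rng) for _ in range(6)]
        scaled = [Graph(g.adjacency * 3.7) for g in graphs]

        def delta_of(gs):
            grid, rows = graph_densities(gs)
            ds = [SpectralDensity(grid, rows[:3].mean(axis=0)),
                  SpectralDensity(grid, rows[3:].mean(axis=0))]
            return delta_statistic(ds)

        assert delta_of(scaled) == pytest.approx(delta_of(graphs), rel=1e-8)
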