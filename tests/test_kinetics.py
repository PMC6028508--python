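"""Division-time distribution and renewal-convolution machinery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.special import gammainc
from scipy.stats import erlang, poisson

from cfsekinetics import (DivisionTimeModel, TimeGrid,
                          cumulative_division_prob_exact, division_cdf,
                          division_pdf, generation_counts,
                          generation_densities, generation_distribution,
                          generation_weights_exact)
from cfsekinetics.kinetics import GridResolutionWarning, auto_max_generation


class TestDivisionTimeModel:
    def test_zero_density_below_minimum_cycle_time(self):
        m = DivisionTimeModel(min_cycle_time=12.0, shape=2.0, scale=3.0)
        assert division_pdf(m, 11.0) == 0.0
        assert division_cdf(m, 12.0) == 0.0

    def test_exponential_special_case(self):
        # shape 1 reduces the shifted gamma to an exponential with rate 1/scale
        m = DivisionTimeModel(0.0, 1.0, 10.0)
        assert division_pdf(m, 0.0) == pytest.approx(0.1)
        assert division_cdf(m, 10.0) == pytest.approx(1 - np.exp(-1), rel=1e-12)

    def test_cdf_matches_incomplete_gamma(self):
        m = DivisionTimeModel(4.0, 2.0, 3.0)
        assert division_cdf(m, 10.0) == pytest.approx(gammainc(2.0, 2.0), rel=1e-12)

    def test_density_integrates_to_one(self):
        m = DivisionTimeModel(5.0, 3.0, 2.0)
        val, _ = quad(lambda t: division_pdf(m, t), 5.0, 5.0 + 200 * 2.0)
        assert val == pytest.approx(1.0, abs=1e-8)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(t_b=st.floats(0.0, 40.0), shape=st.floats(0.3, 10.0),
           scale=st.floats(0.2, 20.0))
    def test_normalization_property(self, t_b, shape, scale):
        m = DivisionTimeModel(t_b, shape, scale)
        # integrate via the cdf far into the tail
        assert m.cdf(t_b + 200 * scale * max(1.0, shape)) == pytest.approx(
            1.0, abs=1e-6)

    @pytest.mark.parametrize("kwargs", [
        dict(min_cycle_time=-1.0, shape=1.0, scale=1.0),
        dict(min_cycle_time=0.0, shape=0.0, scale=1.0),
        dict(min_cycle_time=0.0, shape=1.0, scale=-2.0),
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DivisionTimeModel(**kwargs)


class TestGenerationRecursion:
    def test_first_generation_equals_kernel(self):
        # convolution with the synchronized point mass is the identity
        m = DivisionTimeModel(10.0, 2.0, 3.0)
        grid = TimeGrid(stop=60.0, step=0.05)
        gd = generation_densities(m, grid, n_max=2)
        np.testing.assert_allclose(gd.division_densities[1], m.pdf(grid.times))

    def test_erlang_oracle_for_exponential_cycles(self):
        # zero minimum cycle + shape 1: divisions form a Poisson process,
        # so the n-th division time is Erlang(n, 1/scale)
        sigma = 5.0
        m = DivisionTimeModel(0.0, 1.0, sigma)
        grid = TimeGrid(stop=40.0, step=sigma / 50)
        gd = generation_densities(m, grid, n_max=5)
        for n in range(1, 6):
            expected = erlang(n, scale=sigma).pdf(grid.times)
            np.testing.assert_allclose(gd.division_densities[n], expected,
                                       atol=1e-3)

    def test_near_deterministic_cycle_concentrates_mass(self):
        # vanishing dispersion: the second division happens at ~2 * t_b
        t_b = 10.0
        m = DivisionTimeModel(t_b, 1.0, 0.1)
        grid = TimeGrid(stop=40.0, step=0.002)
        with pytest.warns(GridResolutionWarning):
            gd = generation_densities(m, TimeGrid(stop=40.0, step=1.0), n_max=1)
        gd = generation_densities(m, grid, n_max=2)
        l2 = gd.division_densities[2]
        mode = grid.times[np.argmax(l2)]
        assert mode == pytest.approx(2 * t_b, abs=0.5)

    def test_rejects_bad_generation_count(self):
        m = DivisionTimeModel(10.0, 2.0, 3.0)
        with pytest.raises(ValueError):
            generation_densities(m, TimeGrid(stop=50.0, step=0.1), n_max=0)

    def test_grid_refinement_convergence(self):
        # halving an already-fine step changes each L_n by < 1% in L1
        m = DivisionTimeModel(12.0, 2.0, 4.0)
        coarse = generation_densities(m, TimeGrid(stop=96.0, step=0.08), n_max=4)
        fine = generation_densities(m, TimeGrid(stop=96.0, step=0.04), n_max=4)
        for n in range(1, 5):
            a = coarse.division_densities[n]
            b = fine.division_densities[n][::2]
            l1 = np.trapezoid(np.abs(a - b), dx=0.08)
            assert l1 < 0.01

    def test_uniform_phase_initial_condition(self):
        m = DivisionTimeModel(12.0, 2.0, 4.0)
        grid = TimeGrid(stop=60.0, step=0.05)
        gd = generation_densities(m, grid, n_max=2,
                                  initial_condition="uniform_phase")
        span = m.mean_cycle_time
        inside = grid.times <= span
        np.testing.assert_allclose(gd.division_densities[1][inside], 1 / span)
        assert np.all(gd.division_densities[1][~inside] == 0.0)


@pytest.fixture(scope="module")
def poisson_stack():
    sigma = 10.0
    m = DivisionTimeModel(0.0, 1.0, sigma)
    grid = TimeGrid(stop=60.0, step=sigma / 50)
    return sigma, grid, generation_distribution(m, grid, n_max=10)


class TestCumulativeAndCounts:

    def test_h0_is_one_and_nested(self, poisson_stack):
        _, _, gd = poisson_stack
        cum = gd.cumulative_probs
        assert np.all(cum[0] == 1.0)
        for n in range(cum.shape[0] - 1):
            assert np.all(cum[n + 1] <= cum[n] + 1e-12)
            assert np.all(np.diff(cum[n]) >= -1e-12)

    def test_poisson_oracle_for_cumulative_probs(self, poisson_stack):
        sigma, grid, gd = poisson_stack
        for n in range(8):
            expected = poisson.sf(n - 1, grid.times / sigma)
            np.testing.assert_allclose(gd.cumulative_probs[n], expected,
                                       atol=1e-3)

    def test_no_divisions_at_labeling_instant(self, poisson_stack):
        _, _, gd = poisson_stack
        assert gd.counts[0, 0] == pytest.approx(gd.founders)
        assert np.all(gd.counts[1:, 0] == 0.0)

    def test_single_division_count_poisson_value(self):
        # at t = sigma the division count is Poisson(1): N_1 = 2 N_0 e^{-1}
        sigma = 8.0
        m = DivisionTimeModel(0.0, 1.0, sigma)
        grid = TimeGrid(stop=sigma, step=sigma / 400)
        gd = generation_distribution(m, grid, n_max=8, founders=100.0)
        assert gd.counts[1, -1] == pytest.approx(2 * 100.0 * np.exp(-1),
                                                 rel=1e-3)

    def test_lineage_conservation(self):
        m = DivisionTimeModel(14.0, 2.5, 3.0)
        grid = TimeGrid(stop=120.0, step=0.06)
        gd = generation_distribution(m, grid, founders=500.0)
        n = np.arange(gd.max_generation + 1)
        total = (gd.counts / 2.0 ** n[:, None]).sum(axis=0)
        assert np.max(np.abs(total - 500.0) / 500.0) < 1e-4

    def test_counts_require_cumulative_probs(self):
        m = DivisionTimeModel(10.0, 2.0, 3.0)
        gd = generation_densities(m, TimeGrid(stop=50.0, step=0.05), n_max=3)
        with pytest.raises(ValueError):
            generation_counts(gd)


class TestExactRoute:
    def test_exact_matches_grid_cumulative(self):
        m = DivisionTimeModel(13.0, 1.8, 4.5)
        grid = TimeGrid(stop=140.0, step=0.05)
        gd = generation_distribution(m, grid)
        for n in (1, 3, 5):
            exact = cumulative_division_prob_exact(m, n, grid.times)
            np.testing.assert_allclose(gd.cumulative_probs[n], exact, atol=5e-4)

    def test_generation_weights_match_grid_fractions(self):
        m = DivisionTimeModel(15.0, 2.0, 4.0)
        grid = TimeGrid(stop=144.0, step=0.05)
        gd = generation_distribution(m, grid)
        w_grid = gd.generation_fractions(-1)
        w_exact = generation_weights_exact(m, 144.0, n_max=gd.max_generation)
        np.testing.assert_allclose(w_grid, w_exact, atol=2e-3)

    def test_auto_max_generation_truncates_negligible_tail(self):
        m = DivisionTimeModel(15.0, 2.0, 4.0)
        n_max = auto_max_generation(m, 144.0)
        assert cumulative_division_prob_exact(m, n_max + 1, 144.0) < 1e-6
        assert cumulative_division_prob_exact(m, n_max, 144.0) >= 1e-6
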