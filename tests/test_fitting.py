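"""Least-squares mixture fitting, model comparison and LRC gating."""

import numpy as np
import pytest

from cfsekinetics import (DivisionTimeModel, MixtureParams, forward_model,
                          gate_high_retainers, objective, slow_fraction)
from cfsekinetics.fitting import (FitConfig, FitResult, NonIdentifiableError,
                                  NotConvergedError, fit as fit_histogram,
                                  model_derived_gate)


@pytest.fixture(scope="module")
def noiseless_observation(default_params, init_model, bin_edges):
    obs = forward_model(default_params, init_model, 144.0, bin_edges,
                        method="exact")
    return obs


class TestObjective:
    def test_self_residual_is_zero(self, default_params, init_model,
                                   noiseless_observation):
        val = objective(default_params, noiseless_observation, init_model, 144.0)
        assert val == pytest.approx(0.0, abs=1e-12)

    def test_constant_in_alpha_for_identical_components(self, init_model,
                                                        bin_edges):
        m = DivisionTimeModel(18.0, 2.0, 3.0)
        obs = forward_model(MixtureParams(m, m, 0.0), init_model, 120.0,
                            bin_edges, method="exact")
        vals = [objective(MixtureParams(m, m, a), obs, init_model, 120.0)
                for a in (0.0, 0.2, 0.5)]
        assert max(vals) - min(vals) < 1e-14

    def test_perturbed_scale_increases_objective(self, default_params,
                                                 init_model,
                                                 noiseless_observation):
        p = default_params
        worse = MixtureParams(
            DivisionTimeModel(p.bulk.min_cycle_time, p.bulk.shape,
                              1.5 * p.bulk.scale),
            p.slow, p.slow_fraction)
        base = objective(p, noiseless_observation, init_model, 144.0)
        assert objective(worse, noiseless_observation, init_model, 144.0) > base

    def test_out_of_bounds_is_penalized_but_finite(self, default_params,
                                                   init_model,
                                                   noiseless_observation):
        from cfsekinetics.fitting import _vector_objective
        cfg = FitConfig()
        wild = np.array([1000.0, 500.0, 100.0, 1000.0, 500.0, 100.0, 0.99])
        val = _vector_objective(wild, noiseless_observation, init_model,
                                144.0, cfg)
        assert np.isfinite(val) and val > 10.0


@pytest.fixture(scope="module")
def noiseless_fit(default_params, init_model, bin_edges):
    obs = forward_model(default_params, init_model, 144.0, bin_edges,
                        method="exact")
    return fit_histogram(obs, init_model, 144.0, FitConfig(seed=0))


class TestFit:

    def test_recovers_alpha_and_cycle_times(self, noiseless_fit,
                                            default_params):
        p = noiseless_fit.params
        truth = default_params
        assert p.slow_fraction == pytest.approx(truth.slow_fraction, rel=0.20)
        # the (t_b, sigma, lambda) triplet is only weakly identified, but
        # the mean cycle time of each population is
        assert p.bulk.mean_cycle_time == pytest.approx(
            truth.bulk.mean_cycle_time, rel=0.10)
        assert p.slow.mean_cycle_time == pytest.approx(
            truth.slow.mean_cycle_time, rel=0.10)

    def test_ordering_convention_applied(self, noiseless_fit):
        assert noiseless_fit.params.is_ordered

    def test_nested_model_consistency(self, noiseless_fit):
        # alpha=0 lies inside the mixture space
        assert noiseless_fit.objective <= \
            noiseless_fit.single_population_objective + 1e-12
        assert noiseless_fit.two_populations_supported

    def test_best_start_is_reported(self, noiseless_fit):
        assert noiseless_fit.objective == min(
            s.objective for s in noiseless_fit.per_start)

    def test_deterministic_given_seed(self, default_params, init_model,
                                      bin_edges):
        obs = forward_model(default_params, init_model, 144.0, bin_edges,
                            method="exact")
        cfg = FitConfig(seed=7, n_starts=3, max_iterations=300)
        a = fit_histogram(obs, init_model, 144.0, cfg)
        b = fit_histogram(obs, init_model, 144.0, cfg)
        assert a.objective == b.objective
        np.testing.assert_array_equal(a.params.as_array(), b.params.as_array())

    def test_fixed_parameters_are_held(self, default_params, init_model,
                                       bin_edges):
        obs = forward_model(default_params, init_model, 144.0, bin_edges,
                            method="exact")
        cfg = FitConfig(seed=1, n_starts=2, max_iterations=200,
                        fixed_params={"alpha": 0.015})
        res = fit_histogram(obs, init_model, 144.0, cfg)
        raw = [s.params.slow_fraction for s in res.per_start]
        assert all(a == pytest.approx(0.015, rel=1e-6) for a in raw)

    def test_rejects_nonpositive_chase_time(self, init_model,
                                            noiseless_observation):
        with pytest.raises(ValueError):
            fit_histogram(noiseless_observation, init_model, 0.0, FitConfig())


class TestSlowFraction:
    def _result(self, params, converged=True):
        return FitResult(params=params, objective=1.0, converged=converged,
                         per_start=[])

    def test_accessor_under_convention(self):
        p = MixtureParams(DivisionTimeModel(15, 2, 4),
                          DivisionTimeModel(60, 2, 6), 0.015)
        assert slow_fraction(self._result(p)) == 0.015

    def test_degenerate_components_flagged(self):
        m = DivisionTimeModel(20.0, 2.0, 4.0)
        with pytest.raises(NonIdentifiableError):
            slow_fraction(self._result(MixtureParams(m, m, 0.3)))

    def test_non_converged_flagged(self):
        p = MixtureParams(DivisionTimeModel(15, 2, 4),
                          DivisionTimeModel(60, 2, 6), 0.015)
        with pytest.raises(NotConvergedError):
            slow_fraction(self._result(p, converged=False))


class TestGate:
    def test_quantile_gate_exact_counts(self):
        rng = np.random.default_rng(5)
        events = rng.permutation(np.arange(1.0, 1001.0))
        part = gate_high_retainers(events, quantile=0.99)
        assert part.high.size == 10
        assert part.high.size + part.bulk.size == events.size

    def test_quantile_one_gives_empty_high_set(self):
        part = gate_high_retainers(np.arange(1.0, 101.0), quantile=1.0)
        assert part.high.size == 0

    def test_threshold_above_max_gives_empty_high_set(self):
        part = gate_high_retainers(np.arange(1.0, 101.0), threshold=1e9)
        assert part.high.size == 0

    def test_ties_assigned_to_high_side(self):
        events = np.array([1.0, 2.0, 2.0, 3.0])
        part = gate_high_retainers(events, threshold=2.0)
        assert part.high.size == 3

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            gate_high_retainers(np.array([]), quantile=0.5)

    def test_requires_exactly_one_gate_spec(self):
        with pytest.raises(ValueError):
            gate_high_retainers(np.ones(5))
        with pytest.raises(ValueError):
            gate_high_retainers(np.ones(5), quantile=0.5, threshold=1.0)

    def test_model_derived_gate_in_range(self, default_params, init_model,
                                         bin_edges):
        res = FitResult(params=default_params, objective=0.0, converged=True,
                        per_start=[], config=FitConfig())
        thr = model_derived_gate(res, init_model, 144.0, bin_edges)
        assert bin_edges[0] < thr < bin_edges[-1]
        # the gate sits far above the bulk day-6 mode
        bulk_mode_intensity = np.exp(init_model.log_mean) / 2 ** 6
        assert thr > bulk_mode_intensity
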