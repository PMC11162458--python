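import numpy as np
import pytest

from tempodyn.basis import FilterShape, gamma_kernel
from tempodyn.fitting import (
    TrialSeries,
    average_trials,
    bootstrap_mean,
    crossval_loco,
    fit_alt_model,
    alt_model_components,
    fit_dn,
    fit_linear,
    preprocess,
)
from tempodyn.models import LinearParams, convolve_causal, predict_dn, predict_linear
from tempodyn.stimulus import render


def _make_trials(grid, curves):
    return [TrialSeries(cid, i, grid, v) for cid, vs in curves.items() for i, v in enumerate(vs)]


class TestPreprocess:
    def test_trial_equal_to_blank_mean_becomes_zero(self, grid):
        rng = np.random.default_rng(0)
        blank = rng.normal(size=grid.n_samples)
        trials = [TrialSeries("dur-20", 0, grid, blank.copy())]
        blanks = [TrialSeries("blank", 0, grid, blank.copy())]
        out = preprocess(trials, blanks, shift_ms=0.0)
        np.testing.assert_allclose(out[0].values, 0.0, atol=1e-12)

    def test_every_output_starts_at_zero(self, grid):
        rng = np.random.default_rng(1)
        trials = [TrialSeries(f"c{i}", 0, grid, rng.normal(size=grid.n_samples)) for i in range(5)]
        blanks = [TrialSeries("blank", 0, grid, rng.normal(size=grid.n_samples))]
        for tr in preprocess(trials, blanks):
            assert tr.values[0] == 0.0

    def test_30ms_shift_advances_three_samples(self, grid):
        v = np.arange(grid.n_samples, dtype=float)
        trials = [TrialSeries("c", 0, grid, v)]
        blanks = [TrialSeries("blank", 0, grid, np.zeros(grid.n_samples))]
        out = preprocess(trials, blanks, shift_ms=30.0)[0].values
        # advanced by 3 samples, zero-padded tail, then first entry subtracted
        expected = np.concatenate([v[3:], np.zeros(3)]) - v[3]
        np.testing.assert_allclose(out, expected)

    def test_non_multiple_shift_rejected(self, grid):
        blanks = [TrialSeries("blank", 0, grid, np.zeros(grid.n_samples))]
        with pytest.raises(ValueError, match="multiple of dt"):
            preprocess([], blanks, shift_ms=15.0)


class TestAverageAndBootstrap:
    def test_identical_repeats_average_to_themselves(self, grid):
        v = np.sin(grid.times)
        avg = average_trials(_make_trials(grid, {"c": [v, v, v]}))
        np.testing.assert_allclose(avg["c"].values, v)

    def test_opposite_repeats_cancel(self, grid):
        v = np.sin(grid.times)
        avg = average_trials(_make_trials(grid, {"c": [v, -v]}))
        np.testing.assert_allclose(avg["c"].values, 0.0, atol=1e-15)

    def test_mean_variance_shrinks_as_one_over_n(self, grid):
        rng = np.random.default_rng(7)
        sd = 0.5
        means = []
        for _ in range(400):
            trials = _make_trials(
                grid, {"c": [rng.normal(0, sd, grid.n_samples) for _ in range(8)]}
            )
            means.append(average_trials(trials)["c"].values)
        var = np.var(np.stack(means), axis=0).mean()
        assert var == pytest.approx(sd**2 / 8, rel=0.15)

    def test_bootstrap_deterministic_and_default_count(self, grid):
        rng = np.random.default_rng(2)
        trials = _make_trials(grid, {"c": [rng.normal(size=grid.n_samples) for _ in range(8)]})
        b1 = bootstrap_mean(trials, seed=5)
        b2 = bootstrap_mean(trials, seed=5)
        assert len(b1) == 50
        for d1, d2 in zip(b1, b2):
            np.testing.assert_array_equal(d1["c"].values, d2["c"].values)

    def test_single_repeat_bootstrap_is_constant(self, grid):
        v = np.cos(grid.times)
        boots = bootstrap_mean(_make_trials(grid, {"c": [v]}), n_boot=10, seed=0)
        for b in boots:
            np.testing.assert_array_equal(b["c"].values, v)

    def test_bootstrap_standard_error_matches_closed_form(self, grid):
        rng = np.random.default_rng(11)
        sd, n_rep = 1.0, 8
        trials = _make_trials(
            grid, {"c": [rng.normal(0, sd, grid.n_samples) for _ in range(n_rep)]}
        )
        boots = bootstrap_mean(trials, n_boot=400, seed=3)
        se = np.std(np.stack([b["c"].values for b in boots]), axis=0).mean()
        assert se == pytest.approx(sd / np.sqrt(n_rep), rel=0.2)


class TestFitLinear:
    def test_exact_recovery_from_noiseless_data(self, conditions, fast_basis, slow_basis):
        u = np.linspace(1.0, 0.1, fast_basis.n_funcs)
        rng = np.random.default_rng(4)
        truth = LinearParams(
            u,
            {c.condition_id: rng.normal(size=slow_basis.n_funcs) for c in conditions},
        )
        avg = {
            c.condition_id: predict_linear(c, truth, fast_basis, slow_basis).total
            for c in conditions
        }
        fit = fit_linear(avg, conditions, fast_basis, slow_basis, share_filter=True)
        np.testing.assert_allclose(fit.params.fast_weights, u, atol=1e-8)
        assert fit.loss < 1e-16

    def test_residual_orthogonal_to_design(self, noisy_avg, conditions, fast_basis, slow_basis):
        """The least-squares solution satisfies the normal equations: residuals
        are orthogonal to the shared fast columns (summed over conditions)
        and to each condition's slow columns."""
        fit = fit_linear(noisy_avg, conditions, fast_basis, slow_basis)
        fast_grad = np.zeros(fast_basis.n_funcs)
        scale = 0.0
        for c in conditions:
            cid = c.condition_id
            pred = predict_linear(c, LinearParams(
                fit.params.fast_weights,
                {cid: fit.params.slow_weights_by_condition[cid]},
            ), fast_basis, slow_basis).total
            resid = noisy_avg[cid].values - pred
            F = np.stack([
                convolve_causal(render(c, fast_basis.grid), FilterShape(fast_basis.grid, f))
                for f in fast_basis.functions
            ])
            fast_grad += F @ resid
            scale = max(scale, np.abs(noisy_avg[cid].values).max())
            # per-condition slow columns see only their own condition
            assert np.abs(slow_basis.functions @ resid).max() < 1e-8 * scale * 121
        assert np.abs(fast_grad).max() < 1e-8 * scale * 121

    def test_loss_matches_recomputed_residual(self, noisy_avg, conditions, fast_basis, slow_basis):
        fit = fit_linear(noisy_avg, conditions, fast_basis, slow_basis)
        loss = 0.0
        for c in conditions:
            cid = c.condition_id
            pred = predict_linear(c, LinearParams(
                fit.params.fast_weights,
                {cid: fit.params.slow_weights_by_condition[cid]},
            ), fast_basis, slow_basis).total
            loss += float(np.sum((noisy_avg[cid].values - pred) ** 2))
        assert loss == pytest.approx(fit.loss, rel=1e-9)

    def test_percondition_mode_on_linear_data_gives_identical_filters(
        self, conditions, fast_basis, slow_basis
    ):
        u = np.linspace(1.0, 0.1, fast_basis.n_funcs)
        avg = {
            c.condition_id: predict_linear(c, LinearParams(u), fast_basis).fast
            for c in conditions
        }
        fit = fit_linear(avg, conditions, fast_basis, slow_basis, share_filter=False)
        # the 20/40 ms pulses under-constrain the late basis functions
        # (minimum-norm ambiguity), so compare the well-conditioned conditions
        well_posed = [c for c in conditions if c.is_double or c.pulse_durations_ms[0] >= 80]
        filters = np.stack([
            fit.params[c.condition_id].fast_weights @ fast_basis.functions
            for c in well_posed
        ])
        np.testing.assert_allclose(filters, np.broadcast_to(filters[0], filters.shape), atol=1e-6)


class TestFitDN:
    def test_noiseless_recovery_of_fast_components(
        self, conditions, fast_basis, slow_basis, truth_fast_components
    ):
        fit = fit_dn(truth_fast_components, conditions, fast_basis, slow_basis,
                     n_restarts=2, seed=0)
        for c in conditions:
            got = predict_dn(c, fit.params, fast_basis).fast
            want = truth_fast_components[c.condition_id]
            assert np.linalg.norm(got - want) < 1e-3 * np.linalg.norm(want)

    def test_dn_nests_linear(self, conditions, fast_basis, slow_basis):
        """On linear-generated data the DN fit is at least as good."""
        u = np.linspace(1.0, 0.1, fast_basis.n_funcs)
        avg = {
            c.condition_id: predict_linear(c, LinearParams(u), fast_basis).fast
            for c in conditions
        }
        lin = fit_linear(avg, conditions, fast_basis, slow_basis)
        dn = fit_dn(avg, conditions, fast_basis, slow_basis, n_restarts=1, seed=0)
        assert dn.loss <= lin.loss + 1e-10

    def test_loss_history_non_increasing(self, dn_fit):
        h = dn_fit.loss_history
        assert all(b <= a * (1 + 1e-9) for a, b in zip(h, h[1:]))


class TestAltModels:
    def test_linear_trend_recovers_pure_ramp(self, conditions, grid):
        slope = 0.4
        avg = {c.condition_id: slope * grid.times for c in conditions[:3]}
        params = fit_alt_model(avg, conditions[:3], "linear_trend", grid)
        for cid, p in params.per_condition.items():
            assert p["slope"] == pytest.approx(slope, abs=1e-3)
            assert abs(p["gain"]) < 1e-3

    def test_exponential_trend_on_flat_data_degenerates(self, conditions, grid):
        avg = {conditions[0].condition_id: np.zeros(grid.n_samples)}
        params = fit_alt_model(avg, conditions[:1], "exponential_trend", grid)
        p = params.per_condition[conditions[0].condition_id]
        comp = alt_model_components(params, conditions[0], grid)
        np.testing.assert_allclose(comp.total, 0.0, atol=1e-6)

    def test_components_reconstruct_fit(self, conditions, grid):
        rng = np.random.default_rng(9)
        c = conditions[3]
        filt = FilterShape(grid, gamma_kernel(grid, 2.0, 0.05))
        y = 1.3 * convolve_causal(render(c, grid), filt) + 0.2 * grid.times
        params = fit_alt_model({c.condition_id: y}, [c], "linear_trend", grid)
        comp = alt_model_components(params, c, grid)
        np.testing.assert_allclose(comp.total, y, atol=1e-4)


class TestCrossval:
    def test_noiseless_linear_data_perfect_generalization(
        self, conditions, fast_basis, slow_basis
    ):
        u = np.linspace(1.0, 0.1, fast_basis.n_funcs)
        avg = {
            c.condition_id: predict_linear(c, LinearParams(u), fast_basis).fast
            for c in conditions
        }
        ve = crossval_loco(avg, conditions, "linear", fast_basis, slow_basis)
        assert all(v == pytest.approx(1.0, abs=1e-9) for v in ve.values())

    def test_full_and_fast_only_scores_agree(
        self, conditions, fast_basis, slow_basis, truth_fast_components
    ):
        full = crossval_loco(truth_fast_components, conditions, "linear", fast_basis, slow_basis)
        fast_only = crossval_loco(
            truth_fast_components, conditions, "linear", fast_basis, slow_basis,
            fast_only=True,
        )
        for cid in full:
            assert full[cid] == pytest.approx(fast_only[cid], abs=0.05)

    def test_needs_two_conditions(self, conditions, fast_basis, slow_basis, truth_fast_components):
        one = {conditions[0].condition_id: truth_fast_components[conditions[0].condition_id]}
        with pytest.raises(ValueError):
            crossval_loco(one, conditions[:1], "linear", fast_basis, slow_basis)
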