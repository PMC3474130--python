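"""Constrained montage optimization: objective, constraints, oracle checks."""

from dataclasses import replace

import numpy as np
import pytest

from tdcsteer.errors import ConfigurationError, InvalidParameterError
from tdcsteer.field_ops import total_current
from tdcsteer.optimize import (
    CurrentSteeringModel,
    OptimizerSettings,
    ProblemSpec,
    brute_force_search,
    fix_sign,
    precompute_region_means,
    reduce_pattern,
    scale_pattern,
)
from tdcsteer.roi_stats import region_summary

from conftest import steering_problem


@pytest.fixture(scope="module")
def fitted(steering_model):
    return steering_model.fit()


class TestRegionMeans:
    def test_entries_match_independent_roi_route(self, steering_bundle, basis_current_fields):
        m = precompute_region_means(
            steering_bundle.basis, steering_bundle.tensors, steering_bundle.volume,
            {"target": "target", "avoid": "avoid"},
        )
        vol = steering_bundle.volume
        for i, field in enumerate(basis_current_fields):
            for g, name in enumerate(("target", "avoid")):
                labels = [l for l, n in vol.label_names.items() if n == name]
                ref = region_summary(field, vol, labels).mean
                assert m[i, g] == pytest.approx(ref, rel=1e-12)

    def test_scaling_injection_scales_every_entry(self, steering_bundle):
        basis = steering_bundle.basis
        doubled = type(basis)(
            potentials=2.0 * basis.potentials, montage=basis.montage,
            node_shape=basis.node_shape, spacing_mm=basis.spacing_mm,
            injected_current_A=2 * basis.injected_current_A, solver_tol=basis.solver_tol,
        )
        m1 = precompute_region_means(basis, steering_bundle.tensors,
                                     steering_bundle.volume, {"target": "target"})
        m2 = precompute_region_means(doubled, steering_bundle.tensors,
                                     steering_bundle.volume, {"target": "target"})
        assert np.allclose(m2, 2.0 * m1, rtol=1e-12)

    def test_all_entries_non_negative(self, steering_model):
        assert (steering_model.electrode_region_means() >= 0).all()


class TestObjective:
    def test_zero_pattern_scores_zero(self, steering_model):
        assert steering_model.objective(np.zeros(6)) == 0.0

    def test_even_in_sign_of_the_pattern(self, steering_model):
        rng = np.random.default_rng(9)
        for _ in range(5):
            X = rng.uniform(-2, 2, 6)
            assert steering_model.objective(X) == pytest.approx(
                steering_model.objective(-X), rel=1e-14
            )

    def test_bounded_by_weighted_single_pattern_means(self, steering_model):
        rng = np.random.default_rng(10)
        m_t = steering_model.electrode_region_means()[:, 0]
        for _ in range(100):
            X = rng.uniform(-2, 2, 6)
            assert steering_model.objective(X) <= np.abs(X) @ m_t * (1 + 1e-12)

    def test_exact_gradient_matches_finite_differences(self, steering_model):
        rng = np.random.default_rng(11)
        X = rng.uniform(-1, 1, 6)
        g = steering_model.objective_gradient(X, mode="exact")
        eps = 1e-6
        fd = np.array([
            (steering_model.objective(X + eps * e) - steering_model.objective(X - eps * e))
            / (2 * eps)
            for e in np.eye(6)
        ])
        assert np.allclose(g, fd, rtol=1e-5, atol=1e-10)

    def test_surrogate_gradient_is_gradient_of_the_upper_bound(self, steering_model):
        rng = np.random.default_rng(12)
        X = rng.uniform(0.1, 1.0, 6) * np.array([1, -1, 1, -1, 1, -1])
        m_t = steering_model.electrode_region_means()[:, 0]

        def bound(Y):
            return np.abs(Y) @ m_t

        g = steering_model.objective_gradient(X, mode="surrogate")
        eps = 1e-7
        fd = np.array([(bound(X + eps * e) - bound(X - eps * e)) / (2 * eps) for e in np.eye(6)])
        assert np.allclose(g, fd, rtol=1e-6, atol=1e-12)


class TestConstraints:
    def test_zero_pattern_satisfies_balance_but_violates_c_min(self, steering_model):
        state = {c.cid: c for c in steering_model.constraint_values(np.zeros(6))}
        assert state["1"].violation == 0.0
        assert state["3"].violation == pytest.approx(0.5)  # C_min - 0

    def test_upscaling_eventually_violates_c_max(self, steering_model, fitted):
        X = fitted.X.values
        state = {c.cid: c for c in steering_model.constraint_values(3.0 * X)}
        assert state["4"].violation > 0.0

    def test_magnitude_constraints_identical_at_plus_minus_x(self, steering_model):
        rng = np.random.default_rng(13)
        X = rng.uniform(-1, 1, 6)
        plus = steering_model.constraint_values(X)
        minus = steering_model.constraint_values(-X)
        for cp, cm in zip(plus, minus):
            if cp.cid in ("2", "3", "4", "5"):
                assert cp.value == pytest.approx(cm.value, rel=1e-14)

    def test_avoid_constraint_without_avoid_region_rejected(self):
        with pytest.raises(ConfigurationError):
            ProblemSpec(target=("target",), avoid=(), J_max=1.0,
                        constraints=(True, True, True, True, False))

    def test_inverted_current_window_rejected_before_iteration(self):
        with pytest.raises(ConfigurationError):
            ProblemSpec(target=("target",), C_min=2.0, C_max=0.5,
                        constraints=(True, False, True, True, False))

    def test_disabled_balance_reports_extracranial_remainder(self, steering_model):
        X = np.array([1.0, 0.5, 0.0, 0.0, 0.0, 0.0])
        assert steering_model.extracranial_remainder(X) == pytest.approx(-1.5)


class TestFit:
    def test_result_is_feasible_to_tolerance(self, steering_model, fitted):
        assert fitted.feasible
        # independent re-evaluation of the constraints at the returned X
        assert steering_model.max_violation(fitted.X.values) <= 1e-10

    def test_dominates_random_search_oracle(self, steering_model, fitted):
        bf = brute_force_search(steering_model, 20_000, seed=77)
        assert fitted.objective >= bf.objective * (1 - 0.01)

    def test_positive_weight_biased_toward_target_adjacent_electrode(self, fitted, steering_model):
        m_t = steering_model.electrode_region_means()[:, 0]
        best_electrode = int(np.argmax(m_t))
        X = fitted.X.values if fitted.X.values[best_electrode] >= 0 else -fitted.X.values
        order = np.argsort(-np.abs(X))
        assert best_electrode in order[:2]
        assert X[best_electrode] > 0

    def test_termination_reason_is_enumerated(self, fitted):
        assert fitted.termination_reason in {"iterations", "step", "gradient", "converged"}

    def test_summary_mentions_weights_and_constraints(self, fitted):
        text = fitted.summary()
        assert "mean target |J|" in text
        assert "net_current_zero" in text
        for name in fitted.model.basis.montage.names:
            assert name in text

    def test_deterministic_for_fixed_settings(self, steering_model, fitted):
        again = steering_model.fit()
        assert np.allclose(again.X.values, fitted.X.values, atol=1e-12)
        assert again.objective == pytest.approx(fitted.objective, rel=1e-12)


class TestFixSign:
    def test_mirrored_sign_fixes_give_negated_optima(self, steering_bundle):
        x0 = np.array([0.3, -0.1, 0.05, -0.05, -0.1, -0.1])
        base = steering_problem()
        plus = replace(fix_sign(base, 0, +1), initial_X=x0)
        minus = replace(fix_sign(base, 0, -1), initial_X=-x0)
        rp = CurrentSteeringModel(steering_bundle.basis, steering_bundle.tensors,
                                  steering_bundle.volume, plus).fit()
        rm = CurrentSteeringModel(steering_bundle.basis, steering_bundle.tensors,
                                  steering_bundle.volume, minus).fit()
        assert rp.objective == pytest.approx(rm.objective, rel=1e-9)
        assert np.allclose(rp.X.values, -rm.X.values, atol=1e-9)

    def test_fixing_sign_of_inactive_electrode_costs_nothing(self, steering_bundle,
                                                             steering_model, fitted):
        # the bound agrees with the optimum's own sign, so re-optimizing from
        # the fitted pattern must not lose objective
        weakest = int(np.argmin(np.abs(fitted.X.values)))
        sign = +1 if fitted.X.values[weakest] >= 0 else -1
        prob = replace(fix_sign(steering_problem(), weakest, sign),
                       initial_X=fitted.X.values)
        refit = CurrentSteeringModel(steering_bundle.basis, steering_bundle.tensors,
                                     steering_bundle.volume, prob).fit()
        assert refit.objective >= fitted.objective * (1 - 1e-6)
        state = {c.cid: c for c in refit.constraint_state}
        assert state["sign"].violation == 0.0

    def test_invalid_index_and_conflicts_rejected(self):
        base = steering_problem()
        with pytest.raises(ConfigurationError):
            fix_sign(base, -1, +1)
        with pytest.raises(ConfigurationError):
            fix_sign(base, 7, +1, n_electrodes=6)
        fixed = fix_sign(base, 2, +1)
        with pytest.raises(ConfigurationError):
            fix_sign(fixed, 2, -1)


class TestBruteForce:
    def test_deterministic_and_prefix_monotone(self, steering_model):
        a = brute_force_search(steering_model, 5_000, seed=42)
        b = brute_force_search(steering_model, 5_000, seed=42)
        assert np.array_equal(a.X.values, b.X.values)
        bigger = brute_force_search(steering_model, 20_000, seed=42)
        assert bigger.objective >= a.objective

    def test_returned_sample_is_feasible(self, steering_model):
        bf = brute_force_search(steering_model, 5_000, seed=3)
        assert steering_model.max_violation(bf.X.values) <= 1e-10

    def test_approaches_fit_from_below_on_the_toy_problem(self, steering_model, fitted):
        bf = brute_force_search(steering_model, 50_000, seed=17)
        assert bf.objective <= fitted.objective * (1 + 0.01)

    def test_zero_samples_rejected(self, steering_model):
        with pytest.raises(InvalidParameterError):
            brute_force_search(steering_model, 0, seed=1)


class TestReduceAndScale:
    def test_keeps_largest_magnitudes_and_balances_remainder(self):
        X = np.array([0.8, -0.5, -0.2, -0.1])
        reduced, remainder = reduce_pattern(X, 2)
        assert np.array_equal(reduced.values, [0.8, -0.5, 0.0, 0.0])
        assert remainder == pytest.approx(-0.3)
        assert reduced.values.sum() + remainder == 0.0

    def test_full_k_is_identity_with_balancing_remainder(self):
        X = np.array([0.8, -0.5, -0.2, -0.1])
        reduced, remainder = reduce_pattern(X, 4)
        assert np.array_equal(reduced.values, X)
        assert remainder == pytest.approx(-X.sum())

    def test_single_electrode_keeps_peak_with_opposite_remainder(self):
        X = np.array([0.8, -0.5, -0.2, -0.1])
        reduced, remainder = reduce_pattern(X, 1)
        assert np.array_equal(reduced.values, [0.8, 0.0, 0.0, 0.0])
        assert remainder == pytest.approx(-0.8)

    def test_ties_break_toward_lowest_index(self):
        X = np.array([0.5, -0.5, 0.5, -0.1])
        reduced, _ = reduce_pattern(X, 2)
        assert np.array_equal(reduced.values != 0.0, [True, True, False, False])

    def test_out_of_range_k_rejected(self):
        with pytest.raises(InvalidParameterError):
            reduce_pattern(np.ones(4), 0)
        with pytest.raises(InvalidParameterError):
            reduce_pattern(np.ones(4), 5)

    def test_scale_to_unit_total_current(self):
        X = np.array([1.15, -1.15])
        scaled = scale_pattern(X, 1.0)
        assert np.allclose(scaled.values, X / 1.15)
        assert total_current(scaled) == pytest.approx(1.0)

    def test_scaling_to_current_total_is_identity(self):
        X = np.array([0.4, -0.6, 0.2])
        scaled = scale_pattern(X, total_current(X))
        assert np.allclose(scaled.values, X)

    def test_zero_pattern_cannot_be_scaled(self):
        with pytest.raises(InvalidParameterError):
            scale_pattern(np.zeros(3), 1.0)


class TestSettings:
    @pytest.mark.parametrize("kwargs", [
        {"max_iter": 0}, {"step_tol": 0.0}, {"gradient_tol": -1.0},
        {"feasibility_tol": 0.0}, {"gradient_mode": "mystic"}, {"n_restarts": -1},
    ])
    def test_invalid_settings_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            OptimizerSettings(**kwargs)
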