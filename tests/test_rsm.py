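import numpy as np
import pytest

from releaseopt import (
    ModelTermSet,
    build_model_matrix,
    evaluate_surface,
    fit_design_table,
    fit_surface,
    full_second_order,
    load_example,
    stepwise_select,
)
from releaseopt.rsm import SingularDesignError, Term


def brute_force_ols(X, y):
    """Independent normal-equations solution (x'x)^-1 x'y."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    return np.linalg.inv(X.T @ X) @ X.T @ y


class TestModelMatrix:
    def test_k1_full_second_order_row(self):
        terms = full_second_order(1)
        row = build_model_matrix([[2.0]], terms)
        assert np.allclose(row, [[1, 2, 4]])

    def test_k2_canonical_order(self):
        terms = full_second_order(2)
        assert terms.labels() == ["1", "x1", "x2", "x1^2", "x2^2", "x1*x2"]
        row = build_model_matrix([[1.0, -1.0]], terms)
        assert np.allclose(row, [[1, 1, -1, 1, 1, -1]])

    def test_shape(self, rng):
        settings = rng.uniform(-1, 1, size=(8, 3))
        X = build_model_matrix(settings, full_second_order(3))
        assert X.shape == (8, 10)
        assert np.allclose(X[:, 0], 1)

    def test_duplicate_terms_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ModelTermSet((Term((1, 0)), Term((1, 0))))

    def test_term_parsing_round_trip(self):
        labels = ["1", "x1", "x3", "x1^2", "x1*x3"]
        ts = ModelTermSet.from_strings(labels, 3)
        assert ts.labels() == ["1", "x1", "x3", "x1^2", "x1*x3"]


class TestFitSurface:
    def test_matches_brute_force_on_random_instances(self, rng):
        terms = full_second_order(2)
        for _ in range(25):
            settings = rng.uniform(-1.5, 1.5, size=(10, 2))
            X = build_model_matrix(settings, terms)
            y = rng.normal(size=10)
            fit = fit_surface(X, y, terms)
            assert np.allclose(fit.coefficients, brute_force_ols(X, y), atol=1e-8)

    def test_noiseless_quadratic_recovered_exactly(self, rng):
        terms = full_second_order(3)
        truth = rng.uniform(-2, 2, size=len(terms))
        settings = rng.uniform(-1, 1, size=(15, 3))
        X = build_model_matrix(settings, terms)
        fit = fit_surface(X, X @ truth, terms)
        assert np.allclose(fit.coefficients, truth, atol=1e-8)

    def test_constant_response(self, rng):
        terms = full_second_order(2)
        settings = rng.uniform(-1, 1, size=(9, 2))
        X = build_model_matrix(settings, terms)
        fit = fit_surface(X, np.full(9, 3.25), terms)
        assert fit.coefficients[0] == pytest.approx(3.25, abs=1e-10)
        assert np.allclose(fit.coefficients[1:], 0, atol=1e-10)

    def test_refit_of_fitted_values_is_idempotent(self, rng):
        terms = full_second_order(2)
        settings = rng.uniform(-1, 1, size=(12, 2))
        X = build_model_matrix(settings, terms)
        fit1 = fit_surface(X, rng.normal(size=12), terms)
        fit2 = fit_surface(X, X @ np.array(fit1.coefficients), terms)
        assert np.allclose(fit1.coefficients, fit2.coefficients, atol=1e-10)

    def test_rank_deficiency_names_terms(self):
        terms = full_second_order(1)
        X = build_model_matrix([[1.0], [1.0], [1.0]], terms)
        with pytest.raises(SingularDesignError):
            fit_surface(X, [1.0, 2.0, 3.0], terms)

    def test_underdetermined_rejected(self):
        terms = full_second_order(2)
        X = build_model_matrix([[0.0, 0.0], [1.0, 1.0]], terms)
        with pytest.raises(SingularDesignError, match="runs"):
            fit_surface(X, [1.0, 2.0], terms)


class TestEvaluateSurface:
    def test_fixture_anchors_at_origin(self):
        dic = load_example("diclofenac")
        assert evaluate_surface(dic.surface("mu_y1"), [0, 0, 0]) == 39.929
        met = load_example("metoprolol")
        assert evaluate_surface(met.surface("t50"), [0, 0]) == 6.222

    def test_all_ones_gives_coefficient_sum(self):
        for name in ("diclofenac", "ranitidine"):
            fx = load_example(name)
            ones = np.ones(fx.config.k)
            for s in fx.surfaces:
                assert evaluate_surface(s, ones) == pytest.approx(
                    sum(s.coefficients), abs=1e-10
                )

    def test_fixture_surfaces_finite_on_design(self):
        from releaseopt.optimizer import design_points

        for name in ("diclofenac", "terazosin", "verapamil",
                     "metformin", "ranitidine", "metoprolol"):
            fx = load_example(name)
            pts = design_points(fx.config.factors)
            for s in fx.surfaces:
                assert np.all(np.isfinite(evaluate_surface(s, pts)))

    def test_dimension_mismatch(self):
        fx = load_example("diclofenac")
        with pytest.raises(ValueError):
            evaluate_surface(fx.surfaces[0], [0.0, 0.0])


class TestFitDesignTable:
    def test_zero_noise_recovers_truth(self, dome_truth):
        from releaseopt import SyntheticSpec, factorial_design, generate_experiment

        truth, _ = dome_truth
        table = generate_experiment(
            SyntheticSpec(
                mean_surfaces=truth,
                design=factorial_design([(-1, 0, 1)] * 3),
                sigma=0.0,
                m=3,
                labels=("y1", "y2"),
                seed=1,
            )
        )
        fitted = {s.label: s for s in fit_design_table(table)}
        for t in truth:
            assert np.allclose(
                fitted[t.label].coefficients, t.coefficients, atol=1e-8
            )
        # zero noise: variance, cv and covariance surfaces are identically 0
        for label, s in fitted.items():
            if not label.startswith("mu_"):
                assert np.allclose(s.coefficients, 0, atol=1e-8)


class TestStepwise:
    def test_sparse_truth_selected(self, rng):
        terms = full_second_order(3)
        settings = rng.uniform(-1, 1, size=(60, 3))
        X = build_model_matrix(settings, terms)
        # strong dependence on x1 only
        y = 5.0 + 4.0 * settings[:, 0] + 2.5 * settings[:, 0] ** 2
        y = y + rng.normal(0, 0.2, size=60)
        kept = stepwise_select(X, y, terms)
        labels = kept.labels()
        assert "x1" in labels and "x1^2" in labels
        assert "x2" not in labels and "x3" not in labels

    def test_pure_noise_mostly_keeps_only_intercept(self, rng):
        terms = full_second_order(2)
        settings = rng.uniform(-1, 1, size=(40, 2))
        X = build_model_matrix(settings, terms)
        only_intercept = 0
        n_sim = 40
        for _ in range(n_sim):
            kept = stepwise_select(X, rng.normal(size=40), terms)
            if kept.labels() == ["1"]:
                only_intercept += 1
        # per-factor false-entry rate ~alpha; expect intercept-only ~90% of runs
        assert only_intercept >= int(0.75 * n_sim)

    def test_zero_thresholds_force_full_and_empty(self, rng):
        terms = full_second_order(2)
        settings = rng.uniform(-1, 1, size=(30, 2))
        X = build_model_matrix(settings, terms)
        y = 1 + settings @ np.array([3.0, -2.0]) + rng.normal(0, 0.1, size=30)
        everything = stepwise_select(X, y, terms, alpha_enter=1.0, alpha_remove=1.0)
        assert set(everything.labels()) == set(terms.labels())
        nothing = stepwise_select(X, y, terms, alpha_enter=0.0, alpha_remove=1.0)
        assert nothing.labels() == ["1"]
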