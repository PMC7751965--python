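import math

import numpy as np
import pytest
from scipy import stats

from promreg.stepwise_regression import (
    SelectionConfig,
    cross_validate_model,
    build_predicted_mean_profile,
    forward_select,
    ols_fit,
    select_attendant_features,
)


def normal_equations_oracle(X, y):
    """Independent oracle: explicit (X'X)^-1 X'y with t-distribution p-values."""
    n, p = X.shape
    A = np.hstack([np.ones((n, 1)), X])
    xtx_inv = np.linalg.inv(A.T @ A)
    beta = xtx_inv @ A.T @ y
    resid = y - A @ beta
    df = n - p - 1
    sigma2 = resid @ resid / df
    se = np.sqrt(np.diag(xtx_inv) * sigma2)
    t = beta / se
    pvals = 2 * stats.t.sf(np.abs(t), df)
    return beta, pvals


def greedy_oracle(X, y, steps):
    """Exhaustive greedy: refit OLS per candidate per step, pick max r(fit, y)."""
    selected = []
    for _ in range(steps):
        best_r, best_j = -np.inf, None
        for j in range(X.shape[1]):
            if j in selected:
                continue
            cols = selected + [j]
            A = np.hstack([np.ones((len(y), 1)), X[:, cols]])
            beta, *_ = np.linalg.lstsq(A, y, rcond=None)
            fitted = A @ beta
            r = np.corrcoef(fitted, y)[0, 1]
            if r > best_r + 1e-12:
                best_r, best_j = r, j
        selected.append(best_j)
    return selected


class TestOlsFit:
    def test_exact_proportionality(self, rng):
        x = rng.uniform(0, 1, 50)
        model = ols_fit(x[:, None], 2.0 * x)
        assert model.coefficients[0] == pytest.approx(2.0, abs=1e-12)
        assert model.intercept == pytest.approx(0.0, abs=1e-12)
        assert model.r_op == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        # 3-column toy with integer values, n = 8
        X = np.array(
            [
                [1, 2, 0], [2, 1, 1], [3, 4, 0], [4, 3, 1],
                [5, 6, 0], [6, 5, 1], [7, 9, 0], [8, 7, 1],
            ],
            dtype=float,
        )
        y = np.array([3.0, 5, 4, 8, 7, 12, 9, 15])
        model = ols_fit(X, y)
        beta, pvals = normal_equations_oracle(X, y)
        assert model.intercept == pytest.approx(beta[0], abs=1e-10)
        np.testing.assert_allclose(model.coefficients, beta[1:], atol=1e-10)
        np.testing.assert_allclose(model.p_values, pvals[1:], atol=1e-10)

    def test_null_p_values_not_significant(self):
        """Monte-Carlo: independent noise rarely yields p < 0.001."""
        rng = np.random.default_rng(11)
        n, reps = 1000, 500
        hits = 0
        for _ in range(reps):
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            if ols_fit(x[:, None], y).p_values[0] > 0.001:
                hits += 1
        assert hits >= 0.99 * reps

    def test_singular_design_names_columns(self):
        X = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(np.linalg.LinAlgError, match="x1"):
            ols_fit(X, np.arange(10.0), feature_names=["x0", "x1"])

    def test_too_few_observations(self):
        with pytest.raises(ValueError, match="observations"):
            ols_fit(np.ones((3, 3)), np.ones(3))

    def test_p_value_floor_flagged(self, rng):
        n = 2000
        x = rng.normal(size=n)
        y = 5 * x + rng.normal(0, 1e-4, n)
        model = ols_fit(x[:, None], y)
        assert model.p_values[0] == 1e-300
        assert model.p_floored[0]

    def test_predict_round_trip(self, rng):
        X = rng.normal(size=(60, 3))
        y = X @ [1.0, -2.0, 0.5] + 0.3
        model = ols_fit(X, y)
        np.testing.assert_allclose(model.predict(X), y, atol=1e-10)


class TestForwardSelect:
    def test_picks_exact_copy_first(self, rng):
        y = rng.uniform(0, 3, 100)
        X = np.column_stack([y, rng.normal(size=100)])
        model, trace = forward_select(X, y, SelectionConfig(max_steps=1))
        assert trace.features == ["x0"]
        assert trace.r_op[0] == pytest.approx(1.0)

    def test_matches_exhaustive_greedy_oracle(self):
        rng = np.random.default_rng(4)
        for trial in range(5):
            X = rng.normal(size=(120, 12))
            beta = np.zeros(12)
            beta[[1, 5, 9]] = [0.8, -0.6, 0.4]
            y = X @ beta + rng.normal(0, 0.5, 120)
            model, trace = forward_select(X, y, SelectionConfig(max_steps=4))
            assert model.feature_indices == greedy_oracle(X, y, 4)

    def test_trace_monotone_with_consistent_increments(self, small_dataset):
        model, trace = forward_select(
            small_dataset.feature_matrix, small_dataset.y,
            SelectionConfig(max_steps=10),
        )
        assert all(b - a >= -1e-12 for a, b in zip(trace.r_op, trace.r_op[1:]))
        diffs = [trace.r_op[0]] + [b - a for a, b in zip(trace.r_op, trace.r_op[1:])]
        np.testing.assert_allclose(trace.increments, diffs, atol=1e-12)

    def test_true_effect_recovery(self, small_dataset):
        model, trace = forward_select(
            small_dataset.feature_matrix.binary_only(), small_dataset.y,
            SelectionConfig(max_steps=6),
        )
        for name in small_dataset.config.true_effects:
            assert name in trace.features

    def test_full_steps_attain_full_model_r_op(self, rng):
        X = rng.normal(size=(60, 5))
        y = X @ rng.normal(size=5) + rng.normal(0, 0.2, 60)
        model, trace = forward_select(X, y, SelectionConfig(max_steps=5))
        full = ols_fit(X, y)
        assert trace.r_op[-1] == pytest.approx(full.r_op, abs=1e-10)

    def test_all_constant_errors(self):
        with pytest.raises(ValueError, match="constant"):
            forward_select(np.ones((50, 3)), np.arange(50.0))

    def test_constant_columns_skipped(self, rng):
        y = rng.uniform(0, 1, 80)
        X = np.column_stack([np.full(80, 3.0), y])
        model, trace = forward_select(X, y, SelectionConfig(max_steps=1))
        assert trace.features == ["x1"]

    def test_tie_breaks_to_lowest_index(self, rng):
        y = rng.uniform(0, 1, 50)
        X = np.column_stack([y, y.copy()])
        model, trace = forward_select(X, y, SelectionConfig(max_steps=1))
        assert model.feature_indices == [0]

    def test_zero_row_prediction_is_intercept(self, small_dataset):
        """A TSS with no binding anywhere is predicted at the intercept."""
        model, _ = forward_select(
            small_dataset.feature_matrix, small_dataset.y,
            SelectionConfig(max_steps=5),
        )
        zero_row = np.zeros((1, small_dataset.feature_matrix.n_cols))
        assert model.predict(zero_row)[0] == pytest.approx(model.intercept)

    def test_seeded_rerun_bit_identical(self, small_dataset):
        fm, y = small_dataset.feature_matrix, small_dataset.y
        cfg = SelectionConfig(max_steps=5)
        m1, t1 = forward_select(fm, y, cfg)
        m2, t2 = forward_select(fm, y, cfg)
        assert t1.features == t2.features
        assert t1.r_op == t2.r_op
        np.testing.assert_array_equal(m1.coefficients, m2.coefficients)


class TestCrossValidate:
    def test_noiseless_is_perfect_everywhere(self, rng):
        X = (rng.uniform(size=(300, 6)) < 0.4).astype(float)
        y = 1.0 + X @ np.array([0.5, -0.3, 0.2, 0.0, 0.0, 0.0])
        cv = cross_validate_model(X, y, SelectionConfig(max_steps=3), seed=0)
        assert cv.r_op_full == pytest.approx(1.0, abs=1e-9)
        assert cv.r_op_train == pytest.approx(1.0, abs=1e-9)
        assert cv.r_op_test == pytest.approx(1.0, abs=1e-9)

    def test_seed_determinism(self, small_dataset):
        fm, y = small_dataset.feature_matrix, small_dataset.y
        cfg = SelectionConfig(max_steps=4)
        a = cross_validate_model(fm, y, cfg, seed=9)
        b = cross_validate_model(fm, y, cfg, seed=9)
        assert (a.r_op_full, a.r_op_train, a.r_op_test) == (
            b.r_op_full, b.r_op_train, b.r_op_test)

    def test_requires_200_rows(self, rng):
        with pytest.raises(ValueError, match="200"):
            cross_validate_model(rng.normal(size=(100, 2)), rng.normal(size=100))


class TestPredictedMeanProfile:
    def test_identical_inputs_equal_single_fit(self, small_dataset):
        fm, y = small_dataset.feature_matrix, small_dataset.y
        cfg = SelectionConfig(max_steps=4)
        model, _ = forward_select(fm, y, cfg)
        single = model.predict(fm)
        pmp = build_predicted_mean_profile([(fm, y)] * 3, cfg)
        np.testing.assert_allclose(pmp, single, atol=1e-10)

    def test_simple_average_of_two_fits(self, rng):
        # two designs whose fits are exactly recoverable -> average is exact
        from promreg.feature_builder import FeatureDescriptor, FeatureMatrix

        n = 60
        ids = [f"t{i}" for i in range(n)]
        cols = [FeatureDescriptor(kind="extra", name_override="f")]
        x = rng.uniform(size=n)
        fm = FeatureMatrix(ids, cols, x[:, None], m=0)
        y1, y2 = 2 * x, 4 * x  # fitted profiles equal y1 and y2 exactly
        pmp = build_predicted_mean_profile(
            [(fm, y1), (fm, y2)], SelectionConfig(max_steps=1)
        )
        np.testing.assert_allclose(pmp, 3 * x, atol=1e-10)

    def test_universe_mismatch_errors(self, small_dataset):
        fm = small_dataset.feature_matrix
        other = small_dataset.feature_matrix.subset(range(fm.n_cols))
        other.tss_ids = list(reversed(other.tss_ids))
        with pytest.raises(ValueError, match="universe"):
            build_predicted_mean_profile(
                [(fm, small_dataset.y), (other, small_dataset.y)]
            )


class TestAttendantFeatures:
    def test_pure_noise_extension_empty(self):
        rng = np.random.default_rng(2)
        n = 3000
        signal = rng.normal(size=n)
        y = signal + rng.normal(0, 0.5, n)
        X = np.column_stack([signal] + [rng.normal(size=n) for _ in range(6)])
        model, _ = forward_select(X, y, SelectionConfig(max_steps=1))
        ext = select_attendant_features(X, y, model, SelectionConfig(max_steps=6))
        assert ext == []

    def test_strong_effect_accepted(self):
        rng = np.random.default_rng(3)
        n = 20_000
        x0 = rng.normal(size=n)
        x1 = (rng.uniform(size=n) < 0.3).astype(float)
        y = x0 + 0.5 * x1 + rng.normal(0, 0.3, n)
        X = np.column_stack([x0, x1] + [rng.normal(size=n) for _ in range(4)])
        model, _ = forward_select(X, y, SelectionConfig(max_steps=1))
        ext = select_attendant_features(X, y, model, SelectionConfig(max_steps=5))
        assert [name for name, _, _ in ext][0] == "x1"

    def test_disabled_stop_rule_appends_exactly_max_steps(self, rng):
        n = 200
        X = rng.normal(size=(n, 6))
        y = X[:, 0] + rng.normal(0, 0.5, n)
        model, _ = forward_select(X, y, SelectionConfig(max_steps=1))
        ext = select_attendant_features(
            X, y, model, SelectionConfig(max_steps=2, p_stop=math.inf)
        )
        assert len(ext) == 2
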