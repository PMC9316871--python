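"""Internal/external/Y-scrambling validation and the acceptability rules."""

import numpy as np
import pandas as pd
import pytest

from conftest import normalized_model4_data
from teacqsar.mlr import fit_mlr, fit_statistics, predict
from teacqsar.validation import (acceptability_check, external_validation,
                                 lmo_cv, loo_cv, validation_report, y_scramble)


def brute_force_press(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    press = 0.0
    for i in range(len(y)):
        keep = np.arange(len(y)) != i
        model = fit_mlr(X[keep], y[keep])
        press += float((y[i] - predict(model, X[i][None, :])[0]) ** 2)
    return press


class TestLOO:
    def test_fast_path_equals_explicit_refit(self, rng):
        X = rng.standard_normal((30, 3))
        y = X @ [1.0, -0.5, 0.3] + rng.normal(0, 0.4, 30)
        internal = loo_cv(X, y)
        assert internal.press_cv == pytest.approx(brute_force_press(X, y), abs=1e-10)

    def test_noiseless_data_gives_q2_of_one(self, rng):
        X = rng.standard_normal((25, 2))
        y = X @ [1.0, 2.0] + 0.3
        internal = loo_cv(X, y)
        assert internal.q2_loo == pytest.approx(1.0, abs=1e-10)
        assert internal.press_cv == pytest.approx(0.0, abs=1e-10)

    def test_rmse_cv_is_root_press_over_n(self, rng):
        X = rng.standard_normal((30, 3))
        y = X @ [1.0, -0.5, 0.3] + rng.normal(0, 0.4, 30)
        internal = loo_cv(X, y)
        assert internal.rmse_cv == pytest.approx(np.sqrt(internal.press_cv / 30),
                                                 rel=1e-12)

    def test_q2_below_r2_and_press_above_rss_on_noisy_data(self):
        X, y, _ = normalized_model4_data(seed=4)
        model = fit_mlr(X, y)
        stats = fit_statistics(model, X, y)
        internal = loo_cv(X, y)
        rss = float(((y - predict(model, X)) ** 2).sum())
        assert internal.q2_loo < stats.r2
        assert internal.press_cv > rss


class TestLMO:
    def test_noiseless_data_gives_q2_of_one(self, rng):
        X = rng.standard_normal((30, 3))
        y = X @ [1.0, -1.0, 0.5]
        result = lmo_cv(X, y, leave_fraction=0.3, n_iter=20, seed=0)
        assert result.q2_lmo == pytest.approx(1.0, abs=1e-10)

    def test_deterministic_under_seed(self, rng):
        X = rng.standard_normal((40, 3))
        y = X @ [1.0, -1.0, 0.5] + rng.normal(0, 0.3, 40)
        a = lmo_cv(X, y, 0.3, 50, seed=9)
        b = lmo_cv(X, y, 0.3, 50, seed=9)
        assert np.array_equal(a.per_iteration, b.per_iteration)

    def test_single_left_out_approaches_loo(self, rng):
        X = rng.standard_normal((60, 4))
        y = X @ [1.0, -1.0, 0.5, 0.8] + rng.normal(0, 0.6, 60)
        q2_loo = loo_cv(X, y).q2_loo
        result = lmo_cv(X, y, leave_fraction=1 / 60, n_iter=200, seed=3)
        assert abs(result.q2_lmo - q2_loo) <= 0.05

    def test_retained_set_too_small_rejected(self, rng):
        X = rng.standard_normal((10, 4))
        y = rng.standard_normal(10)
        with pytest.raises(ValueError):
            lmo_cv(X, y, leave_fraction=0.5, n_iter=5, seed=0)


class TestExternalValidation:
    def test_perfect_predictions_score_one(self, rng):
        X = rng.standard_normal((20, 2))
        y = X @ [1.0, -1.0] + 0.2
        model = fit_mlr(X, y)
        ext = external_validation(model, X[:5], y[:5], train_mean=float(y.mean()),
                                  train_tss_per_n=float(y.var()))
        assert ext.rmse_ext == pytest.approx(0.0, abs=1e-10)
        for value in (ext.q2_f1, ext.q2_f2, ext.q2_f3, ext.r2_ext, ext.ccc_ext):
            assert value == pytest.approx(1.0, abs=1e-9)

    def test_hand_example_matches_term_by_term_oracle(self):
        # fixed 3-point external set with known predictions
        y_ext = np.array([0.0, 1.0, 2.0])
        pred = np.array([0.1, 0.9, 2.2])
        train_mean, train_tss_per_n = 1.0, 2.0 / 3.0
        # dummy model returning exactly `pred` for identity descriptors
        X_ext = pd.DataFrame({"a": pred})
        from teacqsar.mlr import MLRModel
        model = MLRModel(["a"], np.array([1.0]), np.array([0.0]), 0.0, 0.0, 10)
        ext = external_validation(model, X_ext, y_ext, train_mean, train_tss_per_n)

        press = 0.1 ** 2 + 0.1 ** 2 + 0.2 ** 2
        assert ext.press_ext == pytest.approx(press, rel=1e-12)
        assert ext.rmse_ext == pytest.approx(np.sqrt(press / 3), rel=1e-12)
        assert ext.mae_ext == pytest.approx((0.1 + 0.1 + 0.2) / 3, rel=1e-12)
        assert ext.q2_f1 == pytest.approx(1 - press / ((1 ** 2) + 0 + (1 ** 2)), rel=1e-12)
        assert ext.q2_f2 == pytest.approx(1 - press / 2.0, rel=1e-12)
        assert ext.q2_f3 == pytest.approx(1 - (press / 3) / (2 / 3), rel=1e-12)
        r = np.corrcoef(y_ext, pred)[0, 1]
        assert ext.r2_ext == pytest.approx(r ** 2, rel=1e-12)
        num = 2 * ((y_ext - 1.0) * (pred - pred.mean())).sum()
        den = (((y_ext - 1.0) ** 2).sum() + ((pred - pred.mean()) ** 2).sum()
               + 3 * (1.0 - pred.mean()) ** 2)
        assert ext.ccc_ext == pytest.approx(num / den, rel=1e-12)

    def test_press_identity(self, rng):
        X = rng.standard_normal((30, 3))
        y = X @ [1.0, -1.0, 0.5] + rng.normal(0, 0.3, 30)
        model = fit_mlr(X[:20], y[:20])
        ext = external_validation(model, X[20:], y[20:],
                                  train_mean=float(y[:20].mean()),
                                  train_tss_per_n=float(y[:20].var()))
        assert ext.rmse_ext ** 2 * 10 == pytest.approx(ext.press_ext, abs=1e-12)

    def test_zero_external_variance_rejected(self, rng):
        X = rng.standard_normal((20, 2))
        y = X @ [1.0, -1.0]
        model = fit_mlr(X, y)
        with pytest.raises(ValueError):
            external_validation(model, X[:3], np.ones(3), 0.0, 1.0)


class TestYScrambling:
    def test_scrambled_statistics_near_chance_on_informative_data(self):
        # noise level chosen so the true fit has R2 around 0.85
        X, y, _ = normalized_model4_data(seed=3, noise_sd=0.029)
        result = y_scramble(X, y, n_permutations=100, seed=3)
        assert result.mean_r2 < 0.2
        assert result.mean_r2 > result.mean_q2

    def test_r2_dominates_q2_pointwise(self, rng):
        X = rng.standard_normal((30, 3))
        y = rng.standard_normal(30)
        result = y_scramble(X, y, n_permutations=50, seed=1)
        assert np.all(result.r2_scrambled >= result.q2_scrambled)

    def test_deterministic_under_seed(self, rng):
        X = rng.standard_normal((25, 2))
        y = rng.standard_normal(25)
        a = y_scramble(X, y, n_permutations=10, seed=5)
        b = y_scramble(X, y, n_permutations=10, seed=5)
        assert np.array_equal(a.r2_scrambled, b.r2_scrambled)

    def test_null_mean_r2_matches_theory(self, rng):
        # E[R2] = p/(n-1) for pure-noise responses
        X = rng.standard_normal((30, 3))
        y = rng.standard_normal(30)
        result = y_scramble(X, y, n_permutations=500, seed=7)
        assert result.mean_r2 == pytest.approx(3 / 29, abs=0.015)

    def test_scrambling_equals_fresh_refit_oracle(self, rng):
        # the projection shortcut must equal refitting on the permuted y
        X = rng.standard_normal((20, 2))
        y = rng.standard_normal(20)
        result = y_scramble(X, y, n_permutations=10, seed=2)
        perm_rng = np.random.default_rng(2)
        for i in range(10):
            perm = perm_rng.permutation(y)
            model = fit_mlr(X, perm)
            stats = fit_statistics(model, X, perm)
            assert result.r2_scrambled[i] == pytest.approx(stats.r2, abs=1e-10)


class TestAcceptability:
    def test_study_four_variable_statistics_pass_primary_rules(self):
        # printed values of the chosen four-variable model
        from teacqsar.mlr import FitStatistics
        from teacqsar.validation import (ExternalValidation, InternalValidation,
                                         YScrambleResult)
        fit = FitStatistics(r2=0.643, r2_adj=0.616, s=0.0428, f_ratio=27.8,
                            p_value=1e-10, rmse_tr=0.041, mae_tr=0.033,
                            ccc_tr=0.886)
        internal = InternalValidation(q2_loo=0.539, press_cv=0.126,
                                      rmse_cv=0.047, mae_cv=0.037, ccc_cv=0.854)
        external = ExternalValidation(rmse_ext=0.030, mae_ext=0.026,
                                      press_ext=0.013, r2_ext=0.859,
                                      q2_f1=0.845, q2_f2=0.843, q2_f3=0.803,
                                      ccc_ext=0.913)
        yscr = YScrambleResult(10, np.full(10, 0.07), np.full(10, -0.1), 0)
        flags = acceptability_check(fit, internal, external, yscr)
        assert flags.r2_ok and flags.r2_ext_ok and flags.ccc_ok
        assert flags.rmse_order_ok and flags.yscr_ok and flags.all_ok

    def test_one_variable_model_fails_r2_rule(self):
        from teacqsar.mlr import FitStatistics
        from teacqsar.validation import (ExternalValidation, InternalValidation,
                                         YScrambleResult)
        fit = FitStatistics(r2=0.316, r2_adj=0.304, s=0.0576, f_ratio=25.9,
                            p_value=1e-5, rmse_tr=0.056, mae_tr=0.042,
                            ccc_tr=0.480)
        internal = InternalValidation(0.227, 0.210, 0.060, 0.044, 0.419)
        external = ExternalValidation(0.049, 0.040, 0.033, 0.657, 0.606,
                                      0.601, 0.498, 0.703)
        yscr = YScrambleResult(10, np.full(10, 0.02), np.full(10, -0.05), 0)
        flags = acceptability_check(fit, internal, external, yscr)
        assert not flags.r2_ok
        assert not flags.all_ok


def test_validation_report_uses_conventional_labels():
    X = np.random.default_rng(0).standard_normal((30, 3))
    y = X @ [1.0, -1.0, 0.5] + np.random.default_rng(1).normal(0, 0.3, 30)
    model = fit_mlr(X, y)
    report = validation_report(fit_statistics(model, X, y), loo_cv(X, y),
                               kxx=0.1, delta_k=0.2)
    for key in ("R2", "R2_adj", "s", "F", "Kxx", "DK", "RMSE_tr", "MAE_tr",
                "CCC_tr", "Q2_LOO", "RMSE_cv", "MAE_cv", "PRESS_cv", "CCC_cv"):
        assert key in report
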