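"""Risk models, concordance, and the cross-validation protocol."""

import warnings

import numpy as np
import pytest

from coclustsurv.containers import SurvivalData
from coclustsurv.models import (
    concordance,
    fit_cox,
    fit_cox_lasso,
    fit_rsf,
    repeated_kfold_cindex,
    split_train_validation,
    sweep_kf,
)
from oracles import harrell_c_pairs


def surv(times, events):
    return SurvivalData(
        np.asarray(times, float), np.asarray(events, int),
        [f"P{i}" for i in range(len(times))],
    )


def exp_surv(risk_group, rng, scale=60.0, multipliers=(1.0, 4.0)):
    t = rng.exponential(scale / np.asarray(multipliers)[risk_group])
    return surv(np.maximum(t, 1e-3), np.ones(len(t)))


class TestSplit:
    def test_study_split_sizes(self):
        tr, va = split_train_validation(154, 0.7, seed=0)
        assert (len(tr), len(va)) == (108, 46)

    def test_event_balance_and_partition(self, rng):
        events = rng.integers(0, 2, 154)
        tr, va = split_train_validation(154, 0.7, stratify_on=events, seed=1)
        assert len(np.intersect1d(tr, va)) == 0
        assert len(tr) + len(va) == 154
        # event proportion differs by at most one subject's worth
        p_tr = events[tr].mean()
        p_va = events[va].mean()
        assert abs(p_tr - p_va) <= 1 / len(va) + 1 / len(tr)

    def test_balanced_small_split(self):
        events = np.array([0, 1] * 5)
        tr, va = split_train_validation(10, 0.5, stratify_on=events, seed=3)
        assert len(tr) == len(va) == 5
        assert events[tr].sum() in (2, 3)

    def test_same_seed_identical(self):
        a = split_train_validation(50, 0.7, seed=9)
        b = split_train_validation(50, 0.7, seed=9)
        np.testing.assert_array_equal(a[0], b[0])

    def test_tiny_stratum_rejected(self):
        with pytest.raises(ValueError):
            split_train_validation(10, 0.7, stratify_on=np.array([1] + [0] * 9), seed=0)


class TestConcordance:
    def test_perfect_inverse_ranking(self):
        s = surv([1, 2, 3, 4], [1, 1, 1, 1])
        assert concordance(np.array([4.0, 3.0, 2.0, 1.0]), s) == 1.0

    def test_constant_risk_is_chance(self):
        s = surv([1, 2, 3, 4], [1, 1, 1, 1])
        assert concordance(np.zeros(4), s) == 0.5

    def test_five_patient_toy_with_censoring(self):
        risk = np.array([3.0, 1.0, 2.0, 2.0, 0.5])
        t = [2, 6, 4, 4, 8]
        e = [1, 1, 0, 1, 1]
        s = surv(t, e)
        assert concordance(risk, s) == pytest.approx(
            harrell_c_pairs(risk, t, e), abs=1e-12
        )

    def test_matches_pair_oracle_on_random_instances(self, rng):
        checked = 0
        while checked < 100:
            n = int(rng.integers(4, 12))
            t = rng.integers(1, 8, n).astype(float)
            e = rng.integers(0, 2, n)
            r = rng.integers(0, 5, n).astype(float)
            try:
                expect = harrell_c_pairs(r, t, e)
            except ValueError:
                continue
            assert concordance(r, surv(t, e)) == pytest.approx(expect, abs=1e-12)
            checked += 1


class TestCox:
    def test_coefficient_sign_recovers_risk_direction(self, rng):
        g = rng.integers(0, 2, 2000)
        s = exp_surv(g, rng)
        model = fit_cox(g.astype(float)[:, None], s)
        assert model.coef[0] > 0

    def test_null_feature_not_significant(self):
        rejections = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            x = r.normal(size=(2000, 1))
            s = exp_surv(r.integers(0, 2, 2000), r)
            model = fit_cox(x, s)
            p = float(model.meta["fitter"].summary["p"].iloc[0])
            rejections += p <= 0.05
        assert 20 - rejections >= 17

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError):
            fit_cox(np.array([[1.0], [2.0]]), surv([1, 2], [0, 0]))

    def test_constant_feature_rejected(self):
        with pytest.raises(ValueError):
            fit_cox(np.ones((10, 1)), surv(np.arange(1, 11), np.ones(10)))


class TestCoxLasso:
    def test_huge_penalty_zeroes_everything(self, rng):
        g = rng.integers(0, 2, 200)
        s = exp_surv(g, rng)
        x = np.column_stack([g.astype(float), rng.normal(size=200)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_cox_lasso(x, s, penalty=1e6)
        assert np.all(model.coef == 0)
        assert model.meta.get("constant_risk") is True

    def test_tiny_penalty_matches_unpenalised_cox(self, rng):
        g = rng.integers(0, 2, 1000)
        s = exp_surv(g, rng)
        x = np.column_stack([g.astype(float), rng.normal(size=1000)])
        lasso = fit_cox_lasso(x, s, penalty=1e-8)
        cox = fit_cox(x, s)
        np.testing.assert_allclose(lasso.coef, cox.coef, atol=1e-4)

    def test_sparsity_recovery_signal_plus_noise(self):
        """One informative feature among ten noise features."""
        wins = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            g = r.integers(0, 2, 300)
            s = exp_surv(g, r)
            x = np.column_stack([g.astype(float), r.normal(size=(300, 10))])
            model = fit_cox_lasso(x, s, seed=seed)
            signal_in = model.coef[0] != 0
            noise_zeroed = np.sum(model.coef[1:] == 0) >= 8
            wins += signal_in and noise_zeroed
        assert wins >= 7

    def test_cindex_criterion_available(self, rng):
        g = rng.integers(0, 2, 150)
        s = exp_surv(g, rng)
        x = np.column_stack([g.astype(float), rng.normal(size=150)])
        model = fit_cox_lasso(x, s, seed=0, criterion="cindex")
        assert model.kind == "cox_lasso"


class TestRSF:
    def test_default_hyperparameters(self, rng):
        g = rng.integers(0, 2, 40)
        model = fit_rsf(g.astype(float)[:, None], exp_surv(g, rng), seed=0)
        assert model.meta["n_trees"] == 500
        assert model.meta["min_leaf"] == 5

    def test_same_seed_identical_predictions(self, rng):
        g = rng.integers(0, 2, 60)
        x = np.column_stack([g.astype(float), rng.normal(size=60)])
        s = exp_surv(g, rng)
        a = fit_rsf(x, s, n_trees=50, seed=4).predict(x)
        b = fit_rsf(x, s, n_trees=50, seed=4).predict(x)
        np.testing.assert_array_equal(a, b)

    def test_strong_binary_signal_gives_high_cv_cindex(self):
        r = np.random.default_rng(0)
        g = r.integers(0, 2, 400)
        t = r.exponential(60.0 / np.where(g == 1, 10.0, 1.0))
        s = surv(np.maximum(t, 1e-3), np.ones(400))
        summary = repeated_kfold_cindex(
            "rsf", g.astype(float)[:, None], s, k=3, reps=2, seed=0, n_trees=100
        )
        assert summary.mean > 0.7

    def test_min_leaf_too_large_rejected(self, rng):
        g = rng.integers(0, 2, 8)
        with pytest.raises(ValueError):
            fit_rsf(g.astype(float)[:, None], exp_surv(g, rng), min_leaf=5, seed=0)


class TestRepeatedCV:
    def test_defaults_follow_protocol(self):
        import inspect

        sig = inspect.signature(repeated_kfold_cindex)
        assert sig.parameters["k"].default == 3
        assert sig.parameters["reps"].default == 100

    def test_null_model_scores_near_half(self):
        r = np.random.default_rng(1)
        g = r.integers(0, 3, 150)
        t = r.exponential(60.0 / (1 + g))
        s = surv(np.maximum(t, 1e-3), np.ones(150))
        x = r.normal(size=(150, 3))  # features independent of survival
        summary = repeated_kfold_cindex("cox", x, s, k=3, reps=10, seed=0)
        assert abs(summary.mean - 0.5) < 0.05

    def test_reproducible_under_seed(self, rng):
        g = rng.integers(0, 2, 90)
        s = exp_surv(g, rng)
        x = g.astype(float)[:, None] + rng.normal(scale=0.5, size=(90, 1))
        a = repeated_kfold_cindex("cox", x, s, k=3, reps=1, seed=3)
        b = repeated_kfold_cindex("cox", x, s, k=3, reps=1, seed=3)
        np.testing.assert_array_equal(a.fold_cindex, b.fold_cindex)

    def test_summary_recomputable_from_folds(self, rng):
        g = rng.integers(0, 2, 90)
        s = exp_surv(g, rng)
        x = g.astype(float)[:, None] + rng.normal(scale=0.5, size=(90, 1))
        summary = repeated_kfold_cindex("cox", x, s, k=3, reps=4, seed=0)
        assert summary.mean == pytest.approx(summary.fold_cindex.mean())
        assert summary.sd == pytest.approx(summary.fold_cindex.std(ddof=1))
        assert ((summary.fold_cindex >= 0) & (summary.fold_cindex <= 1)).all()


class TestSweepKf:
    def test_output_shape_covers_grid_and_models(self, small_cohort):
        from coclustsurv import trifactor as tf

        x = tf.rescale_nonnegative(small_cohort.features)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = sweep_kf(
                x,
                small_cohort.survival,
                k_s=3,
                kf_values=(2, 3),
                model_kinds=("cox", "cox_lasso"),
                reps=1,
                seed=0,
                rsf_trees=20,
                trifactor_opts={"max_iter": 50, "n_restarts": 1},
            )
        assert set(table["kf"]) == {2, 3}
        assert set(table["model"]) == {"cox", "cox_lasso"}
        assert len(table) == 2 * 2 * 3  # kf x model x folds
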