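"""Feature selection: ICC(2,1) against ANOVA oracles, threshold semantics,
greedy redundancy pruning against a reference implementation."""

import numpy as np
import pytest

from coclustsurv.containers import FeatureMatrix
from coclustsurv.selection import (
    correlation_prune,
    export_correlation_matrix,
    filter_by_icc,
    icc_2_1,
    select_features,
)
from oracles import greedy_prune_reference, icc_2_1_anova


def make_fm(values, n_pet=None):
    values = np.asarray(values, dtype=float)
    f = values.shape[1]
    n_pet = f if n_pet is None else n_pet
    names = [f"PET_f{j}" if j < n_pet else f"CT_f{j}" for j in range(f)]
    return FeatureMatrix(values, [f"P{i}" for i in range(values.shape[0])], names)


class TestICC:
    def test_perfect_agreement(self):
        assert icc_2_1(np.array([1, 2, 3, 4]), np.array([1, 2, 3, 4])) == pytest.approx(1.0)

    def test_constant_offset_between_raters(self):
        # frozen from the two-way ANOVA decomposition: MSR=10/3, MSC=2, MSE=0
        got = icc_2_1(np.array([1.0, 2, 3, 4]), np.array([2.0, 3, 4, 5]))
        assert got == pytest.approx(10 / 13, abs=1e-12)

    def test_matches_anova_oracle_on_random_instances(self, rng):
        for _ in range(60):
            n = rng.integers(3, 12)
            x1 = rng.normal(size=n)
            x2 = 0.5 * x1 + rng.normal(scale=rng.uniform(0.1, 2.0), size=n)
            assert icc_2_1(x1, x2) == pytest.approx(icc_2_1_anova(x1, x2), abs=1e-10)

    def test_matches_pingouin_reference(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        for _ in range(10):
            n = int(rng.integers(5, 15))
            x1 = rng.normal(size=n)
            x2 = x1 + rng.normal(scale=0.7, size=n)
            df = pd.DataFrame(
                {
                    "targets": np.tile(np.arange(n), 2),
                    "raters": np.repeat(["a", "b"], n),
                    "scores": np.concatenate([x1, x2]),
                }
            )
            ref = pg.intraclass_corr(df, "targets", "raters", "scores")
            # two-way random, absolute agreement, single rater
            row = ref[ref["Type"].isin(["ICC2", "ICC(A,1)"])]
            icc2 = float(row["ICC"].iloc[0])
            assert icc_2_1(x1, x2) == pytest.approx(icc2, abs=1e-10)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            icc_2_1(np.full(5, 2.0), np.full(5, 2.0))

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            icc_2_1(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


class TestFilterByICC:
    def test_identical_matrices_keep_everything(self, rng):
        x = make_fm(rng.normal(size=(20, 6)))
        report = filter_by_icc(x, x)
        assert report.kept_after_icc == x.feature_names

    def test_noise_feature_dropped(self, rng):
        """A rater-independent noise column fails the 0.75 threshold."""
        drops = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            base = r.normal(size=(500, 3))
            x1 = make_fm(base)
            v2 = base + r.normal(scale=0.1, size=base.shape)
            v2[:, 1] = r.normal(size=500)  # pure noise for rater 2
            x2 = FeatureMatrix(v2, x1.patient_ids, x1.feature_names)
            report = filter_by_icc(x1, x2)
            drops += x1.feature_names[1] not in report.kept_after_icc
        assert drops >= 19

    def test_threshold_one_keeps_only_identical_columns(self, rng):
        base = rng.normal(size=(50, 3))
        v2 = base.copy()
        v2[:, 2] += rng.normal(scale=1e-3, size=50)
        report = filter_by_icc(make_fm(base), make_fm(v2), threshold=1.0)
        assert report.kept_after_icc == []  # strict ">" excludes even ICC == 1

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            filter_by_icc(make_fm(rng.normal(size=(10, 3))), make_fm(rng.normal(size=(10, 4))))


class TestCorrelationPrune:
    def test_exact_duplicate_drops_one(self, rng):
        v = rng.normal(size=(30, 3))
        v[:, 2] = v[:, 0]
        report = correlation_prune(make_fm(v))
        assert len(report.final_features) == 2
        assert len({"PET_f0", "PET_f2"} & set(report.final_features)) == 1

    def test_uncorrelated_features_untouched(self, rng):
        v = rng.normal(size=(2000, 5))  # sample correlations ~ 1/sqrt(n)
        report = correlation_prune(make_fm(v))
        assert report.final_features == [f"PET_f{j}" for j in range(5)]

    def test_matches_reference_greedy_on_small_panels(self, rng):
        """Five-feature panels with induced correlation structure."""
        for trial in range(30):
            r = np.random.default_rng(trial)
            latent = r.normal(size=(40, 2))
            mix = r.normal(size=(2, 5))
            v = latent @ mix + r.normal(scale=r.uniform(0.2, 1.5), size=(40, 5))
            fm = make_fm(v)
            thr = float(r.uniform(0.3, 0.9))
            report = correlation_prune(fm, threshold_pet=thr, threshold_ct=thr)
            corr = np.corrcoef(v, rowvar=False)
            expect = [fm.feature_names[i] for i in greedy_prune_reference(corr, thr)]
            assert report.final_features == expect

    def test_idempotent(self, rng):
        latent = rng.normal(size=(50, 3))
        v = latent @ rng.normal(size=(3, 10)) + rng.normal(scale=0.4, size=(50, 10))
        fm = make_fm(v, n_pet=6)
        first = correlation_prune(fm)
        pruned = fm.select_features(first.final_features)
        second = correlation_prune(pruned)
        assert second.final_features == first.final_features

    def test_surviving_pairs_below_threshold(self, rng):
        latent = rng.normal(size=(60, 2))
        v = latent @ rng.normal(size=(2, 12)) + rng.normal(scale=0.3, size=(60, 12))
        fm = make_fm(v, n_pet=8)
        report = correlation_prune(fm)
        kept = fm.select_features(report.final_features)
        for tag, thr in (("PET", 0.76), ("CT", 0.40)):
            cols = [j for j, m in enumerate(kept.modality) if m == tag]
            if len(cols) < 2:
                continue
            sub = np.corrcoef(kept.values[:, cols], rowvar=False)
            np.fill_diagonal(sub, 0.0)
            assert np.abs(sub).max() < thr

    def test_zero_variance_dropped_first(self, rng):
        v = rng.normal(size=(20, 3))
        v[:, 1] = 7.0
        report = correlation_prune(make_fm(v))
        assert report.dropped_zero_variance == ["PET_f1"]
        assert "PET_f1" not in report.final_features

    def test_modalities_pruned_independently(self, rng):
        """A strong PET-CT correlation alone must not remove anything."""
        base = rng.normal(size=(100, 1))
        v = np.hstack([base, base + rng.normal(scale=0.01, size=(100, 1))])
        fm = make_fm(v, n_pet=1)  # one PET, one CT, |r| ~ 1 across modalities
        report = correlation_prune(fm)
        assert len(report.final_features) == 2


class TestExportCorrelationMatrix:
    def test_symmetric_unit_diagonal(self, rng):
        corr = export_correlation_matrix(make_fm(rng.normal(size=(25, 6))))
        np.testing.assert_allclose(corr, corr.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(corr), 1.0)
        assert np.all(np.abs(corr) <= 1 + 1e-12)

    def test_linear_pair_gives_plus_minus_one(self, rng):
        a = rng.normal(size=30)
        corr = export_correlation_matrix(make_fm(np.column_stack([a, 2 * a + 1, -a])))
        assert corr[0, 1] == pytest.approx(1.0)
        assert corr[0, 2] == pytest.approx(-1.0)

    def test_zero_variance_column_rejected(self):
        with pytest.raises(ValueError):
            export_correlation_matrix(make_fm(np.ones((10, 2))))


def test_full_selection_composes_icc_then_pruning(small_cohort):
    report = select_features(small_cohort.features, small_cohort.features_rater2)
    assert set(report.final_features) <= set(report.kept_after_icc)
    assert report.final_features  # something survives on the default cohort
    dropped = set(report.dropped_redundant)
    assert dropped.isdisjoint(report.final_features)
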