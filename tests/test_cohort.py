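"""Synthetic cohort generator: determinism, block structure, survival law,
censoring calibration, rater replicates and serialization."""

import numpy as np
import pytest

from coclustsurv.cohort import (
    GeneratorConfig,
    generate_cohort,
    generate_rater_replicate,
    read_cohort,
    write_cohort,
)
from coclustsurv.selection import icc_2_1
from conftest import high_snr_config, noiseless_config


class TestGeneratorConfig:
    def test_rejects_too_many_clusters(self):
        with pytest.raises(ValueError):
            GeneratorConfig(n_patients=5, k_s=6, hazard_multipliers=(1, 2, 3, 4, 5, 6))
        with pytest.raises(ValueError):
            GeneratorConfig(n_features_pet=2, n_features_ct=2, k_f=5)

    def test_rejects_bad_censoring_target(self):
        with pytest.raises(ValueError):
            GeneratorConfig(censoring_rate_target=0.95)
        with pytest.raises(ValueError):
            GeneratorConfig(censoring_rate_target=-0.1)

    def test_rejects_non_increasing_hazards(self):
        with pytest.raises(ValueError):
            GeneratorConfig(hazard_multipliers=(1.0, 3.0, 2.0))


class TestGenerateCohort:
    def test_deterministic_regeneration(self):
        cfg = high_snr_config(5)
        a, b = generate_cohort(cfg), generate_cohort(cfg)
        np.testing.assert_array_equal(a.features.values, b.features.values)
        np.testing.assert_array_equal(a.survival.time_months, b.survival.time_months)
        np.testing.assert_array_equal(a.true_patient_labels, b.true_patient_labels)
        assert a.clinical.data.equals(b.clinical.data)

    def test_noiseless_matrix_has_one_value_per_block(self):
        co = generate_cohort(noiseless_config(3))
        distinct = np.unique(co.features.values)
        assert len(distinct) == 3 * 4

    def test_paper_shaped_default_configuration(self):
        cfg = GeneratorConfig()
        assert (cfg.n_patients, cfg.k_s, cfg.k_f) == (154, 3, 9)
        co = generate_cohort(cfg)
        assert co.features.shape == (154, 200)
        assert co.features_rater2.shape == (154, 200)
        assert len(co.survival) == 154

    def test_survival_means_follow_hazard_multipliers(self):
        """Exponential law: group mean survival ratios 1 : 1/2 : 1/4 (LLN)."""
        cfg = GeneratorConfig(
            n_patients=6000, n_features_pet=6, n_features_ct=3, k_s=3, k_f=3,
            hazard_multipliers=(1.0, 2.0, 4.0), censoring_rate_target=0.0, seed=42,
        )
        co = generate_cohort(cfg)
        means = [
            co.survival.time_months[co.true_patient_labels == g].mean() for g in range(3)
        ]
        for g, ratio in ((1, 0.5), (2, 0.25)):
            assert abs(means[g] / means[0] - ratio) / ratio < 0.05

    def test_km_median_converges_to_log2_over_rate(self):
        from coclustsurv.stratify import km_median

        cfg = GeneratorConfig(
            n_patients=15000, n_features_pet=4, n_features_ct=2, k_s=3, k_f=3,
            hazard_multipliers=(1.0, 2.0, 4.0), censoring_rate_target=0.0, seed=9,
        )
        co = generate_cohort(cfg)
        for g, mult in enumerate(cfg.hazard_multipliers):
            med = km_median(co.survival.subset(np.where(co.true_patient_labels == g)[0]))
            theory = np.log(2) * cfg.baseline_scale_months / mult
            assert abs(med - theory) / theory < 0.10

    def test_nlr_identity_every_row(self, default_cohort):
        df = default_cohort.clinical.data
        np.testing.assert_allclose(df["nlr"], df["nc"] / df["lc"], rtol=0, atol=1e-12)

    @pytest.mark.parametrize("target", [0.15, 0.25, 0.40])
    def test_censoring_rate_calibrated(self, target):
        """Realized censoring fraction within 0.1 of the target over seeds."""
        fracs = []
        for seed in range(20):
            cfg = GeneratorConfig(
                n_patients=154, n_features_pet=6, n_features_ct=3, k_s=3, k_f=3,
                censoring_rate_target=target, seed=seed,
            )
            co = generate_cohort(cfg)
            fracs.append(1.0 - co.survival.event.mean())
        assert all(abs(f - target) <= 0.1 for f in fracs)
        assert abs(np.mean(fracs) - target) < 0.05

    def test_truth_labels_in_range(self, small_cohort):
        cfg = small_cohort.config
        assert small_cohort.true_patient_labels.min() >= 0
        assert small_cohort.true_patient_labels.max() < cfg.k_s
        assert small_cohort.true_feature_labels.max() < cfg.k_f


class TestRaterReplicate:
    def test_zero_noise_gives_identity_and_icc_one(self, small_cohort):
        rep = generate_rater_replicate(
            small_cohort.features,
            small_cohort.true_feature_labels,
            np.zeros(small_cohort.config.k_f),
            seed=0,
        )
        np.testing.assert_array_equal(rep.values, small_cohort.features.values)
        col = small_cohort.features.values[:, 0]
        assert icc_2_1(col, rep.values[:, 0]) == pytest.approx(1.0)

    def test_half_signal_noise_gives_icc_near_half(self):
        """sds targeting E[ICC] = 0.5 -> empirical ICC(2,1) in [0.4, 0.6].

        The disagreement noise splits across raters in the two-way ANOVA,
        so the target is hit at sd^2 = 2 var(x), not sd^2 = var(x).
        """
        cfg = high_snr_config(2, n_patients=500)
        co = generate_cohort(cfg)
        x = co.features
        sds = np.array(
            [
                np.sqrt(
                    2.0
                    * np.mean(x.values[:, co.true_feature_labels == b].var(axis=0, ddof=1))
                )
                for b in range(cfg.k_f)
            ]
        )
        rep = generate_rater_replicate(x, co.true_feature_labels, sds, seed=7)
        iccs = [icc_2_1(x.values[:, j], rep.values[:, j]) for j in range(0, x.n_features, 5)]
        assert 0.40 <= np.median(iccs) <= 0.60

    def test_block_icc_separation_drives_filter(self):
        """Expected ICCs (0.9, 0.3) -> threshold 0.75 separates the blocks."""
        from coclustsurv.selection import filter_by_icc

        hits_good = hits_bad = 0
        n_good = n_bad = 0
        for seed in range(20):
            cfg = high_snr_config(
                seed, n_patients=500, k_f=2, n_features_pet=16, n_features_ct=8,
                rater2_target_icc=(0.9, 0.3),
            )
            co = generate_cohort(cfg)
            report = filter_by_icc(co.features, co.features_rater2, threshold=0.75)
            kept = set(report.kept_after_icc)
            for j, name in enumerate(co.features.feature_names):
                if co.true_feature_labels[j] == 0:
                    n_good += 1
                    hits_good += name in kept
                else:
                    n_bad += 1
                    hits_bad += name not in kept
        assert hits_good / n_good >= 0.95  # sensitivity
        assert hits_bad / n_bad >= 0.95  # specificity

    def test_negative_sd_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            generate_rater_replicate(
                small_cohort.features,
                small_cohort.true_feature_labels,
                -np.ones(small_cohort.config.k_f),
                seed=0,
            )


class TestSerialization:
    def test_round_trip_bit_exact(self, tmp_path, small_cohort):
        manifest = write_cohort(small_cohort, tmp_path / "c")
        assert len(manifest) == 6
        back = read_cohort(tmp_path / "c")
        np.testing.assert_array_equal(back.features.values, small_cohort.features.values)
        np.testing.assert_array_equal(
            back.features_rater2.values, small_cohort.features_rater2.values
        )
        np.testing.assert_array_equal(
            back.survival.time_months, small_cohort.survival.time_months
        )
        np.testing.assert_array_equal(
            back.true_patient_labels, small_cohort.true_patient_labels
        )
        np.testing.assert_array_equal(
            back.true_feature_labels, small_cohort.true_feature_labels
        )
        assert back.config == small_cohort.config

    def test_refuses_nonempty_directory(self, tmp_path, small_cohort):
        d = tmp_path / "c"
        d.mkdir()
        (d / "existing.txt").write_text("x")
        with pytest.raises(FileExistsError):
            write_cohort(small_cohort, d)
        write_cohort(small_cohort, d, overwrite=True)  # explicit flag allows it

    def test_serialized_output_is_seed_reproducible(self, tmp_path):
        cfg = noiseless_config(8)
        for name in ("a", "b"):
            write_cohort(generate_cohort(cfg), tmp_path / name)
        for f in ("features.csv", "clinical.csv", "survival.csv", "truth.csv"):
            assert (tmp_path / "a" / f).read_bytes() == (tmp_path / "b" / f).read_bytes()
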