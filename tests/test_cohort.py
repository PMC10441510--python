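"""Synthetic cohort generator: calibration, determinism, bias structure."""

import numpy as np
import pandas as pd
import pytest

from brainpad import BiasSpec, CohortConfig, ScanInventorySpec, cohort
from brainpad.config import ConfigurationError


class TestGenerateCohort:
    def test_moment_calibration_at_large_n(self):
        ages = cohort.generate_cohort(
            CohortConfig(n_participants=10_000, seed=42))["age_years"]
        assert abs(ages.mean() - 53.5) < 0.5
        assert abs(ages.std() - 18.0) < 0.5
        assert abs(np.median(ages) - 56.0) < 1.0

    def test_left_skew_mean_below_median(self):
        ages = cohort.generate_cohort(
            CohortConfig(n_participants=10_000, seed=3))["age_years"]
        assert ages.mean() < np.median(ages)

    def test_truncation_and_single_participant(self):
        df = cohort.generate_cohort(CohortConfig(n_participants=1, seed=0))
        assert len(df) == 1
        assert 15.0 <= df["age_years"].iloc[0] <= 95.0

    def test_all_ages_within_range(self):
        ages = cohort.generate_cohort(
            CohortConfig(n_participants=5000, seed=5))["age_years"]
        assert ages.between(15.0, 95.0).all()

    def test_seed_determinism(self):
        cfg = CohortConfig(n_participants=200, seed=9)
        a = cohort.generate_cohort(cfg)
        b = cohort.generate_cohort(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_infeasible_sd_raises(self):
        with pytest.raises(ConfigurationError):
            CohortConfig(age_sd_target=60.0)

    def test_target_outside_range_raises(self):
        with pytest.raises(ConfigurationError):
            CohortConfig(age_range=(40.0, 95.0), age_mean_target=30.0)


class TestAssignScans:
    def test_single_modality_single_repetition(self, small_cohort):
        spec = ScanInventorySpec(
            modality_scanner_counts={"MPRAGE": {"Avanto": 100}},
            repetition_counts={"MPRAGE": (1.0,)},
            rare_carrier_fraction=0.145,
            reference_n_participants=50)
        inv = cohort.assign_scans(small_cohort.head(50), spec, seed=1)
        assert len(inv) == 50
        assert (inv["modality"] == "MPRAGE").all()
        assert (inv["repetition"] == 1).all()

    def test_deterministic_repetition_law(self, small_cohort):
        spec = ScanInventorySpec(
            modality_scanner_counts={"T1w": {"Aera": 10}, "T2w": {"Aera": 10}},
            repetition_counts={"T1w": (1.0,), "T2w": (1.0,)},
            reference_n_participants=10)
        inv = cohort.assign_scans(small_cohort.head(40), spec, seed=2)
        per = inv.groupby(["participant_id", "modality"]).size()
        assert (per == 1).all()

    def test_counts_match_archive_proportions(self):
        """Per-modality scan counts stay inside 99.7% normal bands of the
        generator's compound inclusion x repetition law."""
        n = 1540
        parts = cohort.generate_cohort(CohortConfig(n_participants=n, seed=21))
        spec = ScanInventorySpec()
        inv = cohort.assign_scans(parts, spec, seed=22)
        counts = inv["modality"].value_counts()
        rare = set(spec.rare_modalities)
        for mod, row in spec.modality_scanner_counts.items():
            if mod in rare:
                continue  # carrier forcing perturbs the rare-modality law
            reps = np.asarray(spec.repetition_counts[mod], dtype=float)
            reps = reps / reps.sum()
            e_r = float(np.sum(reps * np.arange(1, len(reps) + 1)))
            e_r2 = float(np.sum(reps * np.arange(1, len(reps) + 1) ** 2))
            q = sum(row.values()) / e_r / n
            mean = n * q * e_r
            var = n * (q * e_r2 - (q * e_r) ** 2)
            assert abs(counts[mod] - mean) < 3.0 * np.sqrt(var), mod

    def test_rare_modalities_confined_to_carriers(self, inventory):
        rare = set(ScanInventorySpec().rare_modalities)
        carriers = inventory[inventory["modality"].isin(rare)][
            "participant_id"].nunique()
        n = inventory["participant_id"].nunique()
        # carrier fraction 0.145 of 300 participants, binomial 3-sigma band
        assert abs(carriers - 0.145 * n) < 3 * np.sqrt(n * 0.145 * 0.855) + 1

    def test_repetitions_capped_at_four(self, inventory):
        assert inventory["repetition"].between(1, 4).all()

    def test_unique_scan_keys(self, pred_table):
        keys = pred_table[["participant_id", "modality", "repetition"]]
        assert not keys.duplicated().any()

    def test_empty_participants_raises(self):
        with pytest.raises(ValueError):
            cohort.assign_scans(pd.DataFrame(columns=["participant_id"]),
                                ScanInventorySpec(), seed=0)


class TestGeneratePredictions:
    def test_identity_bias_reproduces_age(self, inventory):
        bias = BiasSpec(intercept_alpha=0.0, slope_beta=1.0,
                        subject_effect_sd=0.0, scan_noise_sd=0.0,
                        outlier_fraction=0.0)
        tab = cohort.generate_predictions(inventory, bias, seed=0)
        np.testing.assert_allclose(tab["brain_age_years"], tab["age_years"])

    def test_ols_recovers_generating_bias(self):
        parts = cohort.generate_cohort(CohortConfig(n_participants=5000, seed=31))
        inv = cohort.assign_scans(parts, ScanInventorySpec(), seed=32)
        bias = BiasSpec(subject_effect_sd=0.0, scan_noise_sd=5.0,
                        outlier_fraction=0.0)
        tab = cohort.generate_predictions(inv, bias, seed=33)
        slope, intercept = np.polyfit(tab["age_years"], tab["brain_age_years"], 1)
        assert abs(slope - 0.7) < 0.03
        assert abs(intercept - 15.2) < 1.0

    def test_noiseless_bias_grid_exact(self, inventory):
        for alpha, beta in [(0.0, 1.0), (15.2, 0.7), (-4.0, 1.2)]:
            bias = BiasSpec(intercept_alpha=alpha, slope_beta=beta,
                            subject_effect_sd=0.0, scan_noise_sd=0.0,
                            outlier_fraction=0.0)
            tab = cohort.generate_predictions(inventory, bias, seed=1)
            slope, intercept = np.polyfit(tab["age_years"],
                                          tab["brain_age_years"], 1)
            assert abs(slope - beta) < 1e-9
            assert abs(intercept - alpha) < 1e-7

    def test_subject_effect_constant_within_participant(self, inventory):
        bias = BiasSpec(subject_effect_sd=10.0, scan_noise_sd=0.0,
                        outlier_fraction=0.0)
        tab = cohort.generate_predictions(inventory, bias, seed=2)
        spread = tab.groupby("participant_id")["brain_age_years"].agg(
            lambda v: v.max() - v.min())
        assert spread.max() < 1e-9

    def test_per_slice_median_matches_scan_value(self, inventory):
        bias = BiasSpec(slice_noise_sd=0.0, outlier_fraction=0.0)
        tab, slices = cohort.generate_predictions(inventory.head(20), bias,
                                                  seed=3, n_slices=80)
        assert len(slices) == 20 * 80
        med = slices.groupby("scan_index")["brain_age_years"].median()
        np.testing.assert_allclose(tab["brain_age_years"], med.to_numpy())

    def test_seed_determinism(self, inventory):
        a = cohort.generate_predictions(inventory, BiasSpec(), seed=5)
        b = cohort.generate_predictions(inventory, BiasSpec(), seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_modality_offsets_shift_predictions(self, inventory):
        bias = BiasSpec(modality_offsets={"T2w": 8.0}, subject_effect_sd=0.0,
                        scan_noise_sd=0.0, outlier_fraction=0.0)
        tab = cohort.generate_predictions(inventory, bias, seed=6)
        pad = tab["brain_age_years"] - (15.2 + 0.7 * tab["age_years"])
        assert np.allclose(pad[tab["modality"] == "T2w"], 8.0)
        assert np.allclose(pad[tab["modality"] != "T2w"], 0.0)


class TestVolumes:
    def test_manifest_bookkeeping(self, inventory):
        vols, manifest = cohort.generate_volumes(inventory.head(12), seed=1,
                                                 shape=(24, 24, 24),
                                                 n_corrupted=2)
        assert len(vols) == 12
        assert manifest["corrupted"].sum() == 2
        assert (manifest.loc[manifest["corrupted"], "mode"] != "").all()

    def test_no_corruption_all_clean(self, inventory):
        _, manifest = cohort.generate_volumes(inventory.head(5), seed=2,
                                              shape=(24, 24, 24))
        assert not manifest["corrupted"].any()

    def test_clean_beats_corrupted_on_nmi(self, inventory):
        from brainpad import qc
        vols, manifest = cohort.generate_volumes(inventory.head(14), seed=3,
                                                 shape=(32, 32, 32),
                                                 n_corrupted=4)
        template = cohort.make_template((32, 32, 32))
        nmi = np.array([qc.normalized_mutual_information(v, template)
                        for v in vols])
        corrupted = manifest["corrupted"].to_numpy()
        assert nmi[~corrupted].min() > nmi[corrupted].max()

    def test_invalid_shape_raises(self, inventory):
        with pytest.raises(ValueError):
            cohort.make_template((4, 4, 4))
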