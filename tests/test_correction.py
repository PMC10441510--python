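"""Linear bias models: fitting, correction formula, CV selection, composition."""

import numpy as np
import pandas as pd
import pytest

from brainpad import BiasSpec, CohortConfig, ScanInventorySpec, cohort, correction
from conftest import make_table


@pytest.fixture(scope="module")
def noiseless_biased_table():
    parts = cohort.generate_cohort(CohortConfig(n_participants=400, seed=51))
    inv = cohort.assign_scans(parts, ScanInventorySpec(), seed=52)
    bias = BiasSpec(subject_effect_sd=0.0, scan_noise_sd=0.0,
                    outlier_fraction=0.0)
    return cohort.generate_predictions(inv, bias, seed=53)


class TestFitCorrection:
    def test_recovers_reported_bias_exactly_on_noiseless_data(
            self, noiseless_biased_table):
        model = correction.fit_correction(noiseless_biased_table, "age")
        assert model.intercept == pytest.approx(15.2, abs=1e-8)
        assert model.slope == pytest.approx(0.7, abs=1e-10)

    def test_identity_predictions_give_identity_fit(self):
        tab = make_table([f"p{i}" for i in range(10)],
                         np.linspace(20, 90, 10), "T1w", 1,
                         np.linspace(20, 90, 10))
        model = correction.fit_correction(tab, "age")
        assert model.intercept == pytest.approx(0.0, abs=1e-10)
        assert model.slope == pytest.approx(1.0, abs=1e-12)

    def test_modality_interaction_recovers_offsets(self):
        parts = cohort.generate_cohort(CohortConfig(n_participants=300, seed=54))
        inv = cohort.assign_scans(parts, ScanInventorySpec(), seed=55)
        offsets = {"T1w": 4.0, "T2w": -3.0}
        bias = BiasSpec(modality_offsets=offsets, subject_effect_sd=0.0,
                        scan_noise_sd=0.0, outlier_fraction=0.0)
        tab = cohort.generate_predictions(inv, bias, seed=56)
        model = correction.fit_correction(tab, "age*modality")
        # per-modality fitted intercepts differ by the generated offsets
        for mods, want in [(("T1w", "MPRAGE"), 4.0), (("T2w", "MPRAGE"), -3.0)]:
            a, b = mods
            pred = model.predict(pd.DataFrame(
                {"age_years": [0.0, 0.0], "modality": [a, b],
                 "scanner": ["Aera", "Aera"]}))
            assert pred[0] - pred[1] == pytest.approx(want, abs=1e-7)

    def test_too_few_scans_raises(self):
        tab = make_table(["p0", "p1"], [30, 40], "T1w", 1, [35, 45])
        with pytest.raises(ValueError, match="at least"):
            correction.fit_correction(tab, "age")

    def test_rank_deficiency_names_missing_cell(self):
        tab = make_table([f"p{i}" for i in range(16)],
                         np.linspace(20, 90, 16),
                         ["T1w"] * 8 + ["T2w"] * 8, 1,
                         np.linspace(20, 90, 16),
                         scanner=["Aera"] * 8 + ["Verio"] * 8)
        with pytest.raises(ValueError, match="T1w.*Verio|empty"):
            correction.fit_correction(tab, "age*modality*scanner")

    def test_nested_models_rss_monotone(self, noiseless_biased_table):
        # restrict to a dense modality x scanner sub-design so the full
        # interaction model is estimable
        tab = noiseless_biased_table
        tab = tab[tab["modality"].isin(["MPRAGE", "T1w", "T2w"])
                  & tab["scanner"].isin(["Aera", "Avanto", "Verio"])].copy()
        rng = np.random.default_rng(57)
        tab["brain_age_years"] += rng.normal(0, 4, len(tab))
        rss = {k: correction.fit_correction(tab, k).result.ssr
               for k in correction.CANDIDATE_KINDS}
        assert rss["age*modality*scanner"] <= rss["age*modality"] + 1e-8
        assert rss["age*modality"] <= rss["age"] + 1e-8
        assert rss["age*scanner"] <= rss["age"] + 1e-8


class TestApplyCorrection:
    def test_hand_arithmetic_example(self):
        tab = make_table([f"p{i}" for i in range(4)], [20, 40, 56, 80], "T1w",
                         1, [29.2, 43.2, 54.4, 71.2])  # exactly on 15.2+0.7*age
        model = correction.fit_correction(tab, "age")
        row = make_table(["x"], [56.0], "T1w", 1, [60.0])
        out = correction.apply_correction(row, model)
        # corrected = 56 + 60 - (15.2 + 0.7*56) = 61.6
        assert out["corrected_brain_age_years"].iloc[0] == pytest.approx(61.6)

    def test_points_on_fitted_line_map_to_chronological_age(self):
        tab = make_table([f"p{i}" for i in range(5)], [20, 35, 50, 65, 80],
                         "T1w", 1, 10.0 + 0.8 * np.array([20, 35, 50, 65, 80]))
        model = correction.fit_correction(tab, "age")
        out = correction.apply_correction(tab, model)
        np.testing.assert_allclose(out["corrected_brain_age_years"],
                                   out["age_years"], atol=1e-9)

    def test_residual_identities_on_fitting_set(self, pred_table):
        model = correction.fit_correction(pred_table, "age")
        out = correction.apply_correction(pred_table, model)
        pad = out["corrected_pad_years"]
        assert abs(pad.mean()) < 1e-10
        assert abs(np.corrcoef(pad, out["age_years"])[0, 1]) < 1e-10

    def test_unseen_level_raises(self):
        tab = make_table([f"p{i}" for i in range(12)], np.linspace(20, 90, 12),
                         ["T1w", "T2w"] * 6, 1, np.linspace(25, 85, 12))
        model = correction.fit_correction(tab, "age*modality")
        new = make_table(["q"], [50.0], "IR", 1, [55.0])
        with pytest.raises(ValueError, match="unseen.*IR"):
            correction.apply_correction(new, model)


class TestSelectCorrectionModel:
    def _cv(self, means):
        rows = []
        for kind, mean in zip(correction.CANDIDATE_KINDS, means):
            for fold in (1, 2, 3):
                rows.append({"formula_kind": kind, "fold": fold,
                             "corrected_mae": mean})
        return pd.DataFrame(rows)

    def test_argmin_selection(self):
        cv = self._cv([5.0, 5.2, 5.1, 5.4])
        assert correction.select_correction_model(cv) == "age"

    def test_exact_tie_prefers_simplest(self):
        cv = self._cv([5.0, 5.0, 5.3, 5.4])
        assert correction.select_correction_model(cv) == "age"

    def test_interaction_can_win(self):
        cv = self._cv([5.0, 4.2, 5.3, 5.4])
        assert correction.select_correction_model(cv) == "age*modality"

    def test_missing_fold_raises(self):
        cv = self._cv([5.0, 5.2, 5.1, 5.4]).iloc[:-1]
        with pytest.raises(ValueError, match="missing fold"):
            correction.select_correction_model(cv)

    def test_modality_bias_selects_interaction_out_of_fold(self):
        """With a strong generated modality-specific bias the interaction
        model wins on held-out corrected MAE."""
        parts = cohort.generate_cohort(CohortConfig(n_participants=1200, seed=58))
        inv = cohort.assign_scans(parts, ScanInventorySpec(), seed=59)
        bias = BiasSpec(modality_offsets={"T1w": 12.0, "T2w": -12.0},
                        subject_effect_sd=0.0, scan_noise_sd=3.0,
                        outlier_fraction=0.0)
        tab = cohort.generate_predictions(inv, bias, seed=60)
        pids = tab["participant_id"].unique()
        fit_tab = tab[tab["participant_id"].isin(pids[:600])]
        eval_tab = tab[tab["participant_id"].isin(pids[600:])]
        rows = []
        for kind in ("age", "age*modality"):
            model = correction.fit_correction(fit_tab, kind)
            out = correction.apply_correction(eval_tab, model)
            rows.append({"formula_kind": kind, "fold": 1,
                         "corrected_mae": out["corrected_pad_years"].abs().mean()})
        cv = pd.DataFrame(rows)
        assert correction.select_correction_model(
            cv, candidates=("age", "age*modality")) == "age*modality"


class TestComposeCorrectedPredictor:
    def test_identity_composition(self):
        tab = make_table([f"p{i}" for i in range(6)], np.linspace(20, 90, 6),
                         "T1w", 1, np.linspace(20, 90, 6))
        model = correction.fit_correction(tab, "age")  # (0, 1) identity fit
        composed = correction.compose_corrected_predictor(
            lambda t: t["brain_age_years"].to_numpy(), model)
        np.testing.assert_allclose(composed(tab), tab["brain_age_years"],
                                   atol=1e-9)

    def test_matching_model_debiases_in_expectation(self):
        parts = cohort.generate_cohort(CohortConfig(n_participants=2000, seed=61))
        inv = cohort.assign_scans(parts, ScanInventorySpec(), seed=62)
        bias = BiasSpec(subject_effect_sd=0.0, scan_noise_sd=5.0,
                        outlier_fraction=0.0)
        tab = cohort.generate_predictions(inv, bias, seed=63)
        model = correction.fit_correction(tab, "age")
        composed = correction.compose_corrected_predictor(
            lambda t: t["brain_age_years"].to_numpy(), model)
        corrected_pad = composed(tab) - tab["age_years"].to_numpy()
        assert abs(corrected_pad.mean()) < 0.2

    def test_affine_correction_commutes_with_median(self):
        """Correcting the median of slice predictions equals the median of
        per-slice corrections (the correction is affine in the prediction)."""
        from brainpad.qc import aggregate_slice_predictions
        tab = make_table([f"p{i}" for i in range(5)], [20, 35, 50, 65, 80],
                         "T1w", 1, [29.2, 39.7, 50.9, 60.1, 71.5])
        model = correction.fit_correction(tab, "age")
        rng = np.random.default_rng(64)
        slices = 55.0 + rng.normal(0, 3, 81)
        age = 47.0
        def correct(pred):
            frame = make_table(["z"], [age], "T1w", 1, [pred])
            return correction.apply_correction(
                frame, model)["corrected_brain_age_years"].iloc[0]
        a = correct(aggregate_slice_predictions(slices))
        b = aggregate_slice_predictions([correct(p) for p in slices])
        assert a == pytest.approx(b, abs=1e-9)
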