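"""End-to-end orchestration: simulate -> QC -> split -> predict -> CV model
selection -> correct -> evaluate -> reliability -> group model.

The CNN predictor itself is pluggable and out of scope; two reference
predictors are registered: a table passthrough reading the synthetic
predictions, and a toy volume predictor (affine in slice intensity
statistics) for volume-level runs. All artifacts are written as TSV/JSON and
are byte-reproducible given (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import accuracy, cohort, correction, groupmodels, qc, reliability, splits
from .config import PipelineConfig, N_PREDICTION_SLICES

__all__ = ["run_pipeline", "PipelineResult", "get_predictor", "PREDICTORS"]

logger = logging.getLogger("brainpad.pipeline")


# ---------------------------------------------------------------------------
# Predictor registry
# ---------------------------------------------------------------------------

def passthrough_predictor(table: pd.DataFrame) -> np.ndarray:
    """Read the (synthetic) predictions already present in the table."""
    return table["brain_age_years"].to_numpy()


def toy_volume_predictor(volumes, slice_indices=None) -> list[np.ndarray]:
    """Affine function of per-slice mean intensity: a stand-in predictor for
    end-to-end volume runs. Returns per-slice predictions per volume."""
    out = []
    for vol in volumes:
        data = np.asarray(vol.get_fdata())
        idx = (slice_indices if slice_indices is not None
               else np.arange(data.shape[2]))
        means = data[:, :, idx].mean(axis=(0, 1))
        out.append(20.0 + 0.5 * means)
    return out


PREDICTORS = {
    "passthrough": passthrough_predictor,
    "toy_volume": toy_volume_predictor,
}


def get_predictor(name: str):
    if name not in PREDICTORS:
        raise KeyError(f"unknown predictor {name!r}; available: "
                       f"{sorted(PREDICTORS)}")
    return PREDICTORS[name]


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    config: PipelineConfig
    predictions: pd.DataFrame
    split: pd.DataFrame
    cv_results: pd.DataFrame
    selected_kind: str
    correction_model: correction.CorrectionModel
    corrected_test: pd.DataFrame
    accuracy_report: accuracy.AccuracyReport
    reliability_report: dict
    group_contrasts: pd.DataFrame | None
    group_population_mae: pd.DataFrame | None
    qc_report: pd.DataFrame | None
    seeds: dict[str, int] = field(default_factory=dict)


def _stage(name: str):
    logger.info("[%s] %s", time.strftime("%H:%M:%S"), name)


def _subset(table: pd.DataFrame, pids) -> pd.DataFrame:
    return table[table["participant_id"].isin(set(pids))].copy()


def _corrected_mae(fit_table, eval_table, kind) -> float:
    model = correction.fit_correction(fit_table, kind)
    corrected = correction.apply_correction(eval_table, model)
    return float(corrected["corrected_pad_years"].abs().mean())


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None,
                 predictor: str = "passthrough") -> PipelineResult:
    """Execute every stage on a synthetic cohort.

    The correction model is selected by 3-fold CV inside the training
    subdivision (fitted on cv_bias, scored by corrected MAE on cv_eval),
    re-fitted on the linear-correction subdivision, and evaluated on the
    held-out test subdivision only.
    """
    seed = config.seed
    seeds = {"cohort": seed, "scans": seed + 1, "predictions": seed + 2,
             "split": seed + 3, "cv": seed + 4, "bootstrap": seed + 5,
             "qc": seed + 6, "reliability": seed + 7}

    _stage("simulate: cohort, scan inventory, biased predictions")
    participants = cohort.generate_cohort(
        dataclasses.replace(config.cohort, seed=seeds["cohort"]))
    inventory = cohort.assign_scans(participants, config.inventory, seeds["scans"])
    table = cohort.generate_predictions(inventory, config.bias, seeds["predictions"])

    qc_report = None
    if config.qc_enabled:
        _stage("qc: toy volumes, NMI vs template, review threshold")
        sub = inventory.head(config.qc_n_volumes)
        volumes, manifest = cohort.generate_volumes(
            sub, seeds["qc"], shape=config.qc_volume_shape,
            n_corrupted=config.qc_n_corrupted)
        template = cohort.make_template(config.qc_volume_shape)
        nmis = [qc.normalized_mutual_information(v, template) for v in volumes]
        threshold, flags = qc.propose_qc_threshold(nmis)
        qc_report = manifest.assign(nmi=nmis, flag=flags,
                                    threshold=threshold)

    _stage("split: participant-level subdivisions and CV folds")
    split = splits.assign_subdivisions(inventory, config.split_fractions,
                                       seed=seeds["split"])
    merged = table.merge(split[["participant_id", "subdivision"]],
                         on="participant_id", validate="many_to_one")
    train_participants = split[split["subdivision"] == "train"]
    folds = splits.make_cv_folds(train_participants, k=config.cv_folds,
                                 subsplit=config.cv_subsplit, seed=seeds["cv"])

    _stage("select-correction: cross-validated corrected MAE")
    cv_rows = []
    for it in range(1, config.cv_folds + 1):
        roles = folds[folds["iteration"] == it]
        bias_tab = _subset(merged, roles[roles["role"] == "cv_bias"]["participant_id"])
        eval_tab = _subset(merged, roles[roles["role"] == "cv_eval"]["participant_id"])
        for kind in config.correction_candidates:
            try:
                mae = _corrected_mae(bias_tab, eval_tab, kind)
            except ValueError as exc:
                # interaction cells can be empty inside a small fold; an
                # unfit-table kind cannot win selection
                logger.warning("fold %d kind %s unfit: %s", it, kind, exc)
                mae = np.inf
            cv_rows.append({"iteration": it, "fold": it, "formula_kind": kind,
                            "corrected_mae": mae})
    cv_results = pd.DataFrame(cv_rows)
    selected = correction.select_correction_model(cv_results,
                                                  config.correction_candidates)

    _stage(f"correct: final fit of {selected!r} on the linear-correction set")
    corr_tab = merged[merged["subdivision"] == "linear_correction"]
    model = correction.fit_correction(corr_tab, selected)

    test_tab = merged[merged["subdivision"] == "test"]
    corrected_test = correction.apply_correction(test_tab, model)

    _stage("evaluate: repeated-measures bootstrap on the test set")
    report = accuracy.bootstrap_accuracy(
        corrected_test, value_col="corrected_brain_age_years",
        n_boot_factor=config.n_boot_factor, ci_level=config.ci_level,
        seed=seeds["bootstrap"])

    _stage("reliability: item matrix, alpha, within-subject dispersion")
    rel: dict = {}
    try:
        item = reliability.build_item_matrix(
            corrected_test, min_items_per_row=config.reliability_min_items,
            max_missing_frac=config.reliability_max_missing)
        item = reliability.ensure_pairwise_support(item)
        alpha = reliability.cronbach_alpha(item)
        ci = reliability.alpha_confidence_interval(alpha, item.n_obs, item.k,
                                                   config.ci_level)
        rel = {"alpha": alpha, "alpha_ci": ci, "k_items": item.k,
               "n_participants": item.n_obs}
        rel["within_subject_mad"] = reliability.within_subject_mad(
            corrected_test, seed=seeds["reliability"], ci_level=config.ci_level)
    except ValueError as exc:
        rel = {"error": str(exc)}

    _stage("group model: |brain-PAD| modality contrasts and population MAE")
    contrasts = pop_mae = None
    try:
        ref = ("MPRAGE" if "MPRAGE" in set(corrected_test["modality"])
               else sorted(corrected_test["modality"].unique())[0])
        fit = groupmodels.fit_abs_pad_model(corrected_test, reference=ref,
                                            path=config.group_model_path)
        contrasts = groupmodels.modality_contrasts(fit, config.ci_level)
        pop_mae = groupmodels.population_mae(fit, config.ci_level)
    except (ValueError, RuntimeError) as exc:
        logger.warning("group model skipped: %s", exc)

    result = PipelineResult(
        config=config, predictions=table, split=split, cv_results=cv_results,
        selected_kind=selected, correction_model=model,
        corrected_test=corrected_test, accuracy_report=report,
        reliability_report=rel, group_contrasts=contrasts,
        group_population_mae=pop_mae, qc_report=qc_report, seeds=seeds)

    if out_dir is not None:
        write_artifacts(result, Path(out_dir))
    return result


def _tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_artifacts(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort.write_prediction_table(result.predictions, out_dir / "predictions.tsv")
    _tsv(result.split, out_dir / "split.tsv")
    _tsv(result.cv_results, out_dir / "cv_results.tsv")
    _tsv(result.accuracy_report.table, out_dir / "accuracy.tsv")
    _tsv(result.corrected_test, out_dir / "corrected_test.tsv")
    if result.group_contrasts is not None:
        _tsv(result.group_contrasts, out_dir / "modality_contrasts.tsv")
        _tsv(result.group_population_mae, out_dir / "population_mae.tsv")
    if result.qc_report is not None:
        _tsv(result.qc_report, out_dir / "qc.tsv")
    summary = {
        "selected_correction_model": result.selected_kind,
        "correction_coefficients":
            {k: float(v) for k, v in
             result.correction_model.coefficients.items()},
        "reliability": _jsonable(result.reliability_report),
        "seeds": result.seeds,
        "n_boot": result.accuracy_report.n_boot,
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2,
                                                     sort_keys=True))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return float(obj)
    return obj


def configure_logging(level=logging.INFO) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s: %(message)s"))
    root = logging.getLogger("brainpad")
    if not root.handlers:
        root.addHandler(handler)
    root.setLevel(level)
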