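"""Linear correction of the regression-dilution bias in brain-age predictions.

Noisy imaging features attenuate the fitted relation between predicted and
chronological age (slope < 1): young ages are overestimated and old ages
underestimated. The remedy is an affine correction layer estimated on an
independent sample:

    fit       brain_age ~ prediction            (Wilkinson notation), where
              prediction is chronological age, optionally interacting with
              modality and/or scanner;
    correct   corrected = chronological + brain_age - model(chronological, ...)

so a single new scan can be debiased without a reference sample. Among the
four candidate model forms, the winner is the one minimising the corrected
MAE on held-out evaluation data, averaged across CV folds, with ties broken
toward the simpler form.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

__all__ = [
    "CANDIDATE_KINDS",
    "CorrectionModel",
    "fit_correction",
    "apply_correction",
    "select_correction_model",
    "compose_corrected_predictor",
]

#: Candidate model forms, simplest first (the tie-break order).
CANDIDATE_KINDS: tuple[str, ...] = (
    "age", "age*modality", "age*scanner", "age*modality*scanner")

_KIND_FACTORS = {
    "age": (),
    "age*modality": ("modality",),
    "age*scanner": ("scanner",),
    "age*modality*scanner": ("modality", "scanner"),
}


@dataclass
class CorrectionModel:
    """A fitted linear bias model.

    For the plain ``age`` kind the two coefficients are the reported
    intercept (years) and slope (dimensionless) of the bias.
    """

    formula_kind: str
    result: object                      # statsmodels RegressionResults
    levels: dict[str, list]             # category levels seen at fit time
    n_fit: int

    @property
    def intercept(self) -> float:
        return float(self.result.params["Intercept"])

    @property
    def slope(self) -> float:
        return float(self.result.params["age_years"])

    @property
    def coefficients(self) -> pd.Series:
        return self.result.params

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        self._check_levels(table)
        return np.asarray(self.result.predict(table))

    def _check_levels(self, table: pd.DataFrame) -> None:
        for factor, seen in self.levels.items():
            new = set(table[factor].unique()) - set(seen)
            if new:
                raise ValueError(
                    f"unseen {factor} level(s) {sorted(new)}; the correction "
                    f"model was fitted on {sorted(seen)}")


def _formula(kind: str, table: pd.DataFrame) -> tuple[str, dict[str, list]]:
    if kind not in _KIND_FACTORS:
        raise ValueError(f"unknown formula kind {kind!r}; expected one of "
                         f"{CANDIDATE_KINDS}")
    terms = ["age_years"]
    levels: dict[str, list] = {}
    for factor in _KIND_FACTORS[kind]:
        # treatment coding, most frequent level as reference
        ref = table[factor].value_counts().idxmax()
        terms.append(f'C({factor}, Treatment(reference="{ref}"))')
        levels[factor] = sorted(table[factor].unique())
    rhs = " * ".join(terms)
    return f"brain_age_years ~ {rhs}", levels


def fit_correction(table: pd.DataFrame, formula_kind: str = "age") -> CorrectionModel:
    """OLS fit of predicted brain age on the chosen design (main effects and
    interactions per Wilkinson ``*`` semantics).

    Raises on rank deficiency, naming the empty (modality, scanner) cells or
    single-level factors responsible.
    """
    formula, levels = _formula(formula_kind, table)
    model = smf.ols(formula, data=table)
    n_params = model.exog.shape[1]
    if len(table) < n_params + 1:
        raise ValueError(
            f"need at least {n_params + 1} scans to fit {formula_kind!r}, "
            f"got {len(table)}")
    if np.linalg.matrix_rank(model.exog) < n_params:
        raise ValueError(
            f"design for {formula_kind!r} is rank deficient: "
            f"{_absent_cells(formula_kind, table)}")
    result = model.fit()
    return CorrectionModel(formula_kind=formula_kind, result=result,
                           levels=levels, n_fit=len(table))


def _absent_cells(kind: str, table: pd.DataFrame) -> str:
    factors = _KIND_FACTORS[kind]
    if len(factors) == 2:
        cells = table.groupby(list(factors), observed=True).size()
        full = pd.MultiIndex.from_product(
            [sorted(table[f].unique()) for f in factors], names=factors)
        empty = sorted(set(full) - set(cells.index))
        if empty:
            return f"empty modality x scanner cells {empty}"
    singles = [f for f in factors if table[f].nunique() < 2]
    if singles:
        return f"factor(s) {singles} have a single level"
    return "collinear design"


def apply_correction(table: pd.DataFrame, model: CorrectionModel) -> pd.DataFrame:
    """Apply  corrected = chronological + predicted - model(chronological, ...).

    Adds ``corrected_brain_age_years`` and ``corrected_pad_years``
    (= corrected - chronological) columns; raises on category levels unseen
    at fit time.
    """
    out = table.copy()
    fitted = model.predict(table)
    out["corrected_brain_age_years"] = (
        out["age_years"].to_numpy() + out["brain_age_years"].to_numpy() - fitted)
    out["corrected_pad_years"] = (
        out["corrected_brain_age_years"] - out["age_years"])
    return out


def select_correction_model(cv_results: pd.DataFrame,
                            candidates: Sequence[str] = CANDIDATE_KINDS) -> str:
    """Pick the formula kind with the minimal fold-averaged corrected MAE.

    ``cv_results`` must hold columns (formula_kind, fold, corrected_mae) with
    every candidate evaluated on every fold. Exact ties go to the earlier
    (simpler) entry of ``candidates``.
    """
    required = {"formula_kind", "fold", "corrected_mae"}
    if not required <= set(cv_results.columns):
        raise ValueError(f"cv_results needs columns {sorted(required)}")
    folds = set(cv_results["fold"].unique())
    means = {}
    for kind in candidates:
        sub = cv_results[cv_results["formula_kind"] == kind]
        if set(sub["fold"]) != folds or sub.empty:
            raise ValueError(f"missing fold results for kind {kind!r}")
        means[kind] = float(sub["corrected_mae"].mean())
    best = min(means.values())
    for kind in candidates:  # candidate order = simplicity order
        if means[kind] == best:
            return kind
    raise AssertionError("unreachable")


def compose_corrected_predictor(base_predictor: Callable[[pd.DataFrame], np.ndarray],
                                model: CorrectionModel
                                ) -> Callable[[pd.DataFrame], np.ndarray]:
    """Append the correction layer to a predictor: functional composition,
    no retraining. The composed callable maps a scan table to corrected brain
    ages using the table's chronological ages and category labels."""

    def corrected_predictor(table: pd.DataFrame) -> np.ndarray:
        predicted = np.asarray(base_predictor(table), dtype=float)
        fitted = model.predict(table)
        return table["age_years"].to_numpy() + predicted - fitted

    return corrected_predictor
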