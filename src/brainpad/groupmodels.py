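"""Repeated-measures model of |brain-PAD| and its modality contrasts.

The model is |brain-PAD|_{i,r,m} = s_i + beta_m + eta_i + e_{i,r,m}: subject
effects s_i, modality effects beta_m (treatment-coded against a reference
modality), a per-subject random intercept eta_i and residual error, fitted
by REML with a quasi-Newton optimizer. Subject fixed effects together with
a subject random intercept are not jointly identifiable as literally
written, so the default path uses sum-to-zero coding for the subject fixed
effects (their average is absorbed by the global intercept, which is then
exactly <s_i>) and lets the random-intercept variance collapse toward zero;
two alternative paths drop either the random intercept ("fixed_only", plain
OLS) or the subject fixed effects ("random_only").

From the fit we report:
  * within-subject modality contrasts beta_m - beta_ref (Wald tests);
  * "population" MAE estimates MAE^m = <s_i> + beta_m per modality and their
    unweighted average across modalities as the total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.formula.api as smf

__all__ = ["AbsPadModelFit", "fit_abs_pad_model", "modality_contrasts",
           "population_mae"]

PATHS = ("fixed_and_random", "fixed_only", "random_only")


@dataclass
class AbsPadModelFit:
    result: object                # statsmodels results instance
    reference: str
    modalities: list[str]
    path: str
    random_intercept_sd: float | None
    converged: bool
    df_resid: float

    def _beta_name(self, modality: str) -> str:
        return (f'C(modality, Treatment(reference="{self.reference}"))'
                f"[T.{modality}]")

    def beta(self, modality: str) -> float:
        if modality == self.reference:
            return 0.0
        return float(self.result.params[self._beta_name(modality)])


def fit_abs_pad_model(table: pd.DataFrame, value_col: str = "corrected_pad_years",
                      reference: str = "MPRAGE",
                      path: str = "fixed_and_random") -> AbsPadModelFit:
    """Fit the |brain-PAD| repeated-measures model by REML (or OLS for the
    fixed-only path). Raises on a single-modality table, a missing reference
    level, or non-convergence."""
    if path not in PATHS:
        raise ValueError(f"path must be one of {PATHS}")
    data = table.copy()
    data["abs_pad"] = data[value_col].abs()
    modalities = sorted(data["modality"].unique())
    if len(modalities) < 2:
        raise ValueError("need at least 2 modalities")
    if reference not in modalities:
        raise ValueError(f"reference modality {reference!r} not in data "
                         f"({modalities})")

    mod_term = f'C(modality, Treatment(reference="{reference}"))'
    if path == "fixed_only":
        formula = f"abs_pad ~ {mod_term} + C(participant_id, Sum)"
        result = smf.ols(formula, data=data).fit()
        return AbsPadModelFit(result=result, reference=reference,
                              modalities=modalities, path=path,
                              random_intercept_sd=None, converged=True,
                              df_resid=float(result.df_resid))

    if path == "fixed_and_random":
        formula = f"abs_pad ~ {mod_term} + C(participant_id, Sum)"
    else:  # random_only
        formula = f"abs_pad ~ {mod_term}"
    model = smf.mixedlm(formula, data=data, groups=data["participant_id"],
                        re_formula="1")
    with warnings.catch_warnings():
        # the collapsing random-intercept variance of the default path emits
        # boundary warnings by design
        warnings.simplefilter("ignore")
        result = model.fit(reml=True, method="lbfgs", maxiter=500)
    if not result.converged:
        raise RuntimeError(
            "REML fit did not converge; optimizer message: "
            f"{getattr(result, 'mle_retvals', None)}")
    re_var = float(np.asarray(result.cov_re)[0, 0])
    return AbsPadModelFit(result=result, reference=reference,
                          modalities=modalities, path=path,
                          random_intercept_sd=float(np.sqrt(max(re_var, 0.0))),
                          converged=bool(result.converged),
                          df_resid=float(result.df_resid))


def _fe_cov(fit: AbsPadModelFit) -> tuple[pd.Series, pd.DataFrame]:
    """Fixed-effect coefficients and their covariance (mixed fits carry
    variance-parameter rows that must be dropped)."""
    params = fit.result.params
    cov = fit.result.cov_params()
    fe_names = [n for n in params.index if n in fit.result.model.exog_names]
    return params[fe_names], cov.loc[fe_names, fe_names]


def _wald(estimate: float, se: float, df: float, level: float = 0.95):
    tcrit = stats.t.ppf(0.5 + level / 2.0, df)
    p = 2.0 * stats.t.sf(abs(estimate) / se, df) if se > 0 else (
        0.0 if estimate != 0 else 1.0)
    return estimate - tcrit * se, estimate + tcrit * se, p


def modality_contrasts(fit: AbsPadModelFit, level: float = 0.95) -> pd.DataFrame:
    """Per-modality contrast beta_m - beta_ref with Wald CI and p-value
    (residual degrees of freedom). The reference row is 0 by construction."""
    params, cov = _fe_cov(fit)
    rows = []
    for m in fit.modalities:
        if m == fit.reference:
            rows.append({"modality": m, "estimate": 0.0, "se": 0.0,
                         "ci_lo": 0.0, "ci_hi": 0.0, "p_value": np.nan})
            continue
        name = fit._beta_name(m)
        est = float(params[name])
        se = float(np.sqrt(cov.loc[name, name]))
        lo, hi, p = _wald(est, se, fit.df_resid, level)
        rows.append({"modality": m, "estimate": est, "se": se,
                     "ci_lo": lo, "ci_hi": hi, "p_value": p})
    return pd.DataFrame(rows)


def population_mae(fit: AbsPadModelFit, level: float = 0.95) -> pd.DataFrame:
    """Model-based MAE estimates: MAE^m = <s_i> + beta_m.

    With sum-coded subject fixed effects, <s_i> is the model intercept, so
    each per-modality estimate is a linear contrast Intercept + beta_m; the
    total is the unweighted mean of the per-modality values, independent of
    modality sample sizes. CIs are Wald intervals from the contrast variance.
    """
    params, cov = _fe_cov(fit)
    names = list(params.index)

    def contrast_row(label: str, weights: dict[str, float]):
        c = np.array([weights.get(n, 0.0) for n in names])
        est = float(c @ params.to_numpy())
        se = float(np.sqrt(c @ cov.to_numpy() @ c))
        lo, hi, _ = _wald(est, se, fit.df_resid, level)
        return {"modality": label, "estimate": est, "se": se,
                "ci_lo": lo, "ci_hi": hi}

    rows = []
    total_w: dict[str, float] = {"Intercept": 1.0}
    M = len(fit.modalities)
    for m in fit.modalities:
        w = {"Intercept": 1.0}
        if m != fit.reference:
            w[fit._beta_name(m)] = 1.0
            total_w[fit._beta_name(m)] = total_w.get(fit._beta_name(m), 0.0) + 1.0 / M
        rows.append(contrast_row(m, w))
    rows.append(contrast_row("total", total_w))
    return pd.DataFrame(rows)
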