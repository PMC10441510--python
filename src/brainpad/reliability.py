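"""Internal consistency of corrected brain-PADs across modalities and
repeated scans.

Corrected brain-PAD values are reorganised into a participants x items
matrix, items being (modality, repetition) pairs — up to 6 modality variants
times 4 repetitions = 24 items. Participants with fewer than 3 observed
items are dropped, then items missing in more than 95% of the remaining
rows. Cronbach's alpha

    alpha = k/(k-1) * (1 - trace(C) / sum_ij C_ij)

uses the pairwise-deletion covariance matrix C (each entry from the rows
where both items are observed, n-1 denominator). Its confidence interval is
computed from the F distribution via the inverse survival function,

    lower = 1 - (1 - alpha) * F_isf(a/2,   df1, df2)
    upper = 1 - (1 - alpha) * F_isf(1-a/2, df1, df2)

with a = 1 - level, df1 = n_obs - 1, df2 = df1 * k, exactly as printed in
the protocol this package reproduces; note this convention can differ from
Feldt-type intervals found elsewhere (see docs/methods.md).

The complementary dispersion measure is the within-subject mean absolute
deviation of corrected brain-PADs around each participant's own mean,
averaged across participants, with a percentile bootstrap CI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ItemMatrix",
    "build_item_matrix",
    "ensure_pairwise_support",
    "cronbach_alpha",
    "alpha_confidence_interval",
    "within_subject_mad",
]


@dataclass
class ItemMatrix:
    """Participants x (modality, repetition) matrix of corrected brain-PADs."""

    X: pd.DataFrame          # rows: participant_id; columns: (modality, repetition)
    k: int                   # items after filtering
    n_obs: int               # participants after filtering

    def __post_init__(self) -> None:
        assert self.X.shape == (self.n_obs, self.k)


def build_item_matrix(table: pd.DataFrame, value_col: str = "corrected_pad_years",
                      min_items_per_row: int = 3,
                      max_missing_frac: float = 0.95) -> ItemMatrix:
    """Pivot corrected brain-PADs into the item matrix and apply the row
    filter (participants with < ``min_items_per_row`` items) followed by the
    column filter (items with > ``max_missing_frac`` missing)."""
    X = table.pivot_table(index="participant_id", columns=["modality", "repetition"],
                          values=value_col, aggfunc="mean")
    X = X[X.notna().sum(axis=1) >= min_items_per_row]
    if X.empty:
        raise ValueError("all participants filtered out (fewer than "
                         f"{min_items_per_row} items each)")
    missing_frac = X.isna().mean(axis=0)
    X = X.loc[:, missing_frac <= max_missing_frac]
    return ItemMatrix(X=X, k=X.shape[1], n_obs=X.shape[0])


def ensure_pairwise_support(item: ItemMatrix, min_joint: int = 2) -> ItemMatrix:
    """Greedily drop the sparsest items until every item pair has at least
    ``min_joint`` joint observations (a precondition of the pairwise-deletion
    covariance). Small samples can satisfy the stated row/column filters yet
    leave rare item pairs with no overlap; this guard makes alpha computable
    at desk scale without touching the filter rules themselves."""
    X = item.X
    while X.shape[1] >= 2:
        present = X.notna().to_numpy().astype(int)
        joint = present.T @ present
        np.fill_diagonal(joint, min_joint)
        if joint.min() >= min_joint:
            break
        X = X.drop(columns=[X.columns[int(np.argmin(present.sum(axis=0)))]])
    if X.shape[1] < 2:
        raise ValueError("fewer than 2 items retain pairwise support")
    X = X[X.notna().sum(axis=1) >= 1]
    return ItemMatrix(X=X, k=X.shape[1], n_obs=X.shape[0])


def _item_frame(X) -> pd.DataFrame:
    if isinstance(X, ItemMatrix):
        return X.X
    return pd.DataFrame(np.asarray(X, dtype=float))


def cronbach_alpha(X) -> float:
    """alpha = k/(k-1) * (1 - trace(C)/sum(C)), C by pairwise deletion."""
    frame = _item_frame(X)
    k = frame.shape[1]
    if k < 2:
        raise ValueError("need at least 2 items")
    present = frame.notna().to_numpy().astype(int)
    joint = present.T @ present
    if np.any(joint < 2):
        i, j = np.argwhere(joint < 2)[0]
        raise ValueError(
            f"item pair ({frame.columns[i]}, {frame.columns[j]}) has fewer "
            "than 2 joint observations; pairwise covariance undefined")
    C = frame.cov(min_periods=2).to_numpy()
    total = float(C.sum())
    if total <= 0:
        raise ValueError("covariance matrix sums to <= 0; alpha unstable")
    return (k / (k - 1)) * (1.0 - float(np.trace(C)) / total)


def alpha_confidence_interval(alpha_hat: float, n_obs: int, k: int,
                              level: float = 0.95) -> tuple[float, float]:
    """F-based CI for Cronbach's alpha (inverse-survival convention)."""
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    if n_obs < 2 or k < 2:
        raise ValueError("need n_obs >= 2 and k >= 2")
    a = 1.0 - level
    df1 = n_obs - 1
    df2 = df1 * k
    lower = 1.0 - (1.0 - alpha_hat) * stats.f.isf(a / 2.0, df1, df2)
    upper = 1.0 - (1.0 - alpha_hat) * stats.f.isf(1.0 - a / 2.0, df1, df2)
    return float(lower), float(upper)


def within_subject_mad(table: pd.DataFrame, exclude_modalities=(),
                       value_col: str = "corrected_pad_years",
                       n_boot: int = 2000, ci_level: float = 0.95,
                       seed: int = 0) -> dict:
    """Mean absolute deviation of corrected brain-PADs around each
    participant's own mean, averaged across participants.

    ``exclude_modalities`` removes those items before anything else;
    participants left with a single item drop out. Returns the
    cross-participant mean with a percentile bootstrap CI over participants.
    """
    sub = table[~table["modality"].isin(set(exclude_modalities))]
    per = sub.groupby("participant_id")[value_col].agg(
        lambda v: np.abs(v - v.mean()).mean() if len(v) >= 2 else np.nan)
    per = per.dropna()
    if per.empty:
        raise ValueError("no participant has >= 2 items after the filter")
    values = per.to_numpy()
    rng = np.random.default_rng(seed)
    idx = rng.integers(len(values), size=(n_boot, len(values)))
    boot_means = values[idx].mean(axis=1)
    lo, hi = 100 * (1 - ci_level) / 2, 100 * (1 + ci_level) / 2
    return {
        "mean": float(values.mean()),
        "ci": (float(np.percentile(boot_means, lo)),
               float(np.percentile(boot_means, hi))),
        "n_participants": int(len(values)),
        "n_boot": n_boot,
    }
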