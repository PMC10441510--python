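"""Accuracy metrics under a repeated-measures bootstrap.

MAE, Pearson correlation and a constrained R² are reported per modality and
pooled. Because participants contribute up to N_r repeated scans, each
bootstrap replicate first draws one repetition uniformly at random per
participant (and per modality when pooling) and then resamples participants
with replacement; the replicate mean and 2.5/97.5 percentiles give the point
estimate and 95% CI. Default replicate counts are ``factor x N_r`` per
modality and ``factor x N_r x N_m`` pooled, with factor = 10,000.

The constrained R² scores the fixed line brain_age = chronological_age
(slope 1, intercept 0): R² = 1 - RSS/TSS with RSS the residuals around the
identity line and TSS around the mean predicted age. It can be negative when
the identity line fits worse than the mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["constrained_r2", "bootstrap_accuracy", "AccuracyReport"]

_BATCH = 2000  # replicates per vectorised batch (memory bound)


def constrained_r2(brain_ages, chronological_ages) -> float:
    """1 - RSS/TSS for the slope-1, intercept-0 model."""
    y = np.asarray(brain_ages, dtype=float)
    x = np.asarray(chronological_ages, dtype=float)
    if y.size < 2 or y.size != x.size:
        raise ValueError("need >= 2 paired observations")
    rss = float(np.sum((y - x) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0.0:
        raise ValueError("TSS is zero (constant brain ages); R2 undefined")
    return 1.0 - rss / tss


@dataclass
class AccuracyReport:
    """Bootstrap accuracy per modality (and pooled)."""

    table: pd.DataFrame        # rows: modality or 'pooled'; metric mean + CI
    n_boot: dict[str, int] = field(default_factory=dict)
    seed: int = 0
    ci_level: float = 0.95


def _metrics_from_draws(pred: np.ndarray, ages: np.ndarray,
                        weights: np.ndarray | None = None) -> dict[str, np.ndarray]:
    """Rowwise MAE / correlation / constrained R2 for a (B, n) batch.

    ``weights`` (B, n) counts how often each column is in the resample; None
    means plain unweighted rows.
    """
    if weights is None:
        weights = np.ones_like(pred)
    w_sum = weights.sum(axis=1)
    abs_err = np.sum(weights * np.abs(pred - ages), axis=1) / w_sum
    mx = np.sum(weights * ages, axis=1) / w_sum
    my = np.sum(weights * pred, axis=1) / w_sum
    cov = np.sum(weights * (ages - mx[:, None]) * (pred - my[:, None]), axis=1)
    vx = np.sum(weights * (ages - mx[:, None]) ** 2, axis=1)
    vy = np.sum(weights * (pred - my[:, None]) ** 2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = cov / np.sqrt(vx * vy)
        rss = np.sum(weights * (pred - ages) ** 2, axis=1)
        r2 = 1.0 - rss / vy
    return {"mae": abs_err, "correlation": corr, "r2": r2}


def _bootstrap_cell(values: list[np.ndarray], ages: np.ndarray, n_boot: int,
                    rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Replicates for one cell: one unit (participant[, modality]) per column.

    ``values[i]`` holds the repeated measures of unit ``i``; ``ages`` aligns
    with units. Participant resampling is expressed through multinomial
    weights, which is equivalent to index resampling.
    """
    n_units = len(values)
    counts = np.array([len(v) for v in values])
    width = counts.max()
    mat = np.zeros((n_units, width))
    for i, v in enumerate(values):
        mat[i, : len(v)] = v
    out: dict[str, list[np.ndarray]] = {"mae": [], "correlation": [], "r2": []}
    done = 0
    while done < n_boot:
        b = min(_BATCH, n_boot - done)
        rep_choice = (rng.random((b, n_units)) * counts).astype(np.intp)
        drawn = np.take_along_axis(
            np.broadcast_to(mat, (b, n_units, width)), rep_choice[:, :, None],
            axis=2)[:, :, 0]
        weights = rng.multinomial(n_units, np.full(n_units, 1.0 / n_units),
                                  size=b).astype(float)
        batch = _metrics_from_draws(drawn, np.broadcast_to(ages, (b, n_units)),
                                    weights)
        for k in out:
            out[k].append(batch[k])
        done += b
    return {k: np.concatenate(v) for k, v in out.items()}


def _summarise(draws: dict[str, np.ndarray], ci_level: float) -> dict[str, float]:
    lo, hi = 100 * (1 - ci_level) / 2, 100 * (1 + ci_level) / 2
    row = {}
    for k, v in draws.items():
        finite = v[np.isfinite(v)]
        if finite.size == 0:
            row[k], row[f"{k}_lo"], row[f"{k}_hi"] = np.nan, np.nan, np.nan
        else:
            row[k] = float(finite.mean())
            row[f"{k}_lo"] = float(np.percentile(finite, lo))
            row[f"{k}_hi"] = float(np.percentile(finite, hi))
    return row


def bootstrap_accuracy(table: pd.DataFrame, value_col: str = "brain_age_years",
                       per_modality: bool = True, pooled: bool = True,
                       n_boot_factor: int = 10_000, n_boot: int | None = None,
                       ci_level: float = 0.95, seed: int = 0,
                       min_participants: int = 2) -> AccuracyReport:
    """Repeated-measures bootstrap of MAE / correlation / constrained R².

    ``n_boot`` overrides the ``factor x N_r (x N_m)`` default for desk-scale
    runs. Cells with fewer than ``min_participants`` participants are omitted
    with a warning. Deterministic given ``seed``.
    """
    import warnings

    rng = np.random.default_rng(seed)
    n_r = int(table["repetition"].max())
    rows, n_boot_used = [], {}

    def cell_units(sub: pd.DataFrame, by_modality: bool):
        keys = ["participant_id", "modality"] if by_modality else ["participant_id"]
        groups = sub.groupby(keys, sort=True)
        values = [g[value_col].to_numpy() for _, g in groups]
        ages = np.array([g["age_years"].iloc[0] for _, g in groups])
        return values, ages

    if per_modality:
        for modality, sub in table.groupby("modality", sort=True):
            if sub["participant_id"].nunique() < min_participants:
                warnings.warn(f"modality {modality!r} has fewer than "
                              f"{min_participants} participants; omitted")
                continue
            nb = n_boot if n_boot is not None else n_boot_factor * n_r
            values, ages = cell_units(sub, by_modality=False)
            draws = _bootstrap_cell(values, ages, nb, rng)
            rows.append({"cell": modality, **_summarise(draws, ci_level),
                         "n_participants": len(values)})
            n_boot_used[str(modality)] = nb

    if pooled:
        n_m = table["modality"].nunique()
        nb = n_boot if n_boot is not None else n_boot_factor * n_r * n_m
        values, unit_ages = cell_units(table, by_modality=True)
        # pooled resampling unit is the participant: group the
        # (participant, modality) items by participant
        pids = [key[0] for key in
                table.groupby(["participant_id", "modality"], sort=True).groups]
        draws = _bootstrap_pooled(values, unit_ages, pids, nb, rng)
        rows.append({"cell": "pooled", **_summarise(draws, ci_level),
                     "n_participants": len(set(pids))})
        n_boot_used["pooled"] = nb

    report = pd.DataFrame(rows)
    return AccuracyReport(table=report, n_boot=n_boot_used, seed=seed,
                          ci_level=ci_level)


def _bootstrap_pooled(values: list[np.ndarray], ages: np.ndarray,
                      participant_of_item: list, n_boot: int,
                      rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Pooled replicates: draw one repetition per (participant, modality)
    item, then resample participants; a resampled participant brings all its
    items, expressed as multinomial weights shared across its items."""
    n_items = len(values)
    counts = np.array([len(v) for v in values])
    width = counts.max()
    mat = np.zeros((n_items, width))
    for i, v in enumerate(values):
        mat[i, : len(v)] = v
    uniq, item_to_part = np.unique(participant_of_item, return_inverse=True)
    n_parts = len(uniq)
    out: dict[str, list[np.ndarray]] = {"mae": [], "correlation": [], "r2": []}
    done = 0
    while done < n_boot:
        b = min(_BATCH, n_boot - done)
        rep_choice = (rng.random((b, n_items)) * counts).astype(np.intp)
        drawn = np.take_along_axis(
            np.broadcast_to(mat, (b, n_items, width)), rep_choice[:, :, None],
            axis=2)[:, :, 0]
        part_w = rng.multinomial(n_parts, np.full(n_parts, 1.0 / n_parts),
                                 size=b).astype(float)
        weights = part_w[:, item_to_part]
        batch = _metrics_from_draws(drawn, np.broadcast_to(ages, (b, n_items)),
                                    weights)
        for k in out:
            out[k].append(batch[k])
        done += b
    return {k: np.concatenate(v) for k, v in out.items()}
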