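"""Participant-level data subdivisions and cross-validation folds.

The whole sample splits 77% / 8.5% / 14.5% into training, linear-correction
and held-out test subdivisions at the participant level (every scan inherits
its participant's subdivision). Participants carrying any rare modality
(available only at test time) fill the test subdivision first; training is
drawn from participants holding exclusively the common modalities.
Within strata defined by scans-per-participant, assignment is randomised so
each subdivision sees roughly the same distribution of scan counts.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .config import COMMON_MODALITIES, RARE_MODALITIES

__all__ = ["largest_remainder", "assign_subdivisions", "make_cv_folds"]

SUBDIVISIONS = ("train", "linear_correction", "test")


def largest_remainder(n: int, fractions) -> list[int]:
    """Apportion ``n`` into integer counts proportional to ``fractions``
    (Hamilton's method): exact total, deterministic."""
    fractions = np.asarray(fractions, dtype=float)
    if n < 0 or np.any(fractions < 0):
        raise ValueError("n and fractions must be non-negative")
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    raw = n * fractions
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:remainder]] += 1
    return counts.tolist()


def _scan_count_bins(n_scans: pd.Series, n_bins: int = 4) -> pd.Series:
    """Quantile bins of scans-per-participant used as balance strata."""
    try:
        return pd.qcut(n_scans.rank(method="first"), q=n_bins, labels=False)
    except ValueError:
        return pd.Series(np.zeros(len(n_scans), dtype=int), index=n_scans.index)


def _stratified_allocate(pool: pd.DataFrame, targets: dict[str, int],
                         rng: np.random.Generator) -> pd.Series:
    """Assign each pool row a label so global label counts equal ``targets``,
    spreading every scan-count stratum across labels proportionally."""
    assert sum(targets.values()) == len(pool)
    labels = list(targets)
    remaining = np.array([targets[lab] for lab in labels], dtype=int)
    assignment = pd.Series(index=pool.index, dtype=object)
    bins = _scan_count_bins(pool["n_scans"])
    total_left = len(pool)
    for _, idx in pool.groupby(bins, sort=True).groups.items():
        idx = list(idx)
        order = rng.permutation(len(idx))
        m = len(idx)
        if total_left == m:
            alloc = remaining.copy()
        else:
            frac = remaining / total_left
            alloc = np.array(largest_remainder(m, frac / frac.sum()))
            alloc = np.minimum(alloc, remaining)
            # distribute any shortfall to labels with capacity
            short = m - alloc.sum()
            while short > 0:
                j = int(np.argmax(remaining - alloc))
                alloc[j] += 1
                short -= 1
        pos = 0
        for j, lab in enumerate(labels):
            take = [idx[order[p]] for p in range(pos, pos + alloc[j])]
            assignment.loc[take] = lab
            pos += alloc[j]
        remaining -= alloc
        total_left -= m
    return assignment


def _participant_frame(inventory: pd.DataFrame) -> pd.DataFrame:
    per = inventory.groupby("participant_id").agg(
        n_scans=("modality", "size"),
        modalities=("modality", lambda s: frozenset(s)),
    ).reset_index()
    return per


def assign_subdivisions(inventory: pd.DataFrame,
                        fractions=(0.77, 0.085, 0.145),
                        seed: int = 0,
                        rare_modalities=RARE_MODALITIES) -> pd.DataFrame:
    """Partition participants into train / linear_correction / test.

    ``inventory`` is a scan-level table (participant_id, modality, ...).
    Subdivision sizes follow largest-remainder apportionment of ``fractions``.
    Rare-modality carriers are test-eligible and fill the test subdivision
    first; any surplus carriers land in the linear-correction set (never
    training). A shortfall of carriers is covered from the common-modality
    pool with a warning. Returns one row per participant with columns
    (participant_id, n_scans, subdivision); deterministic given ``seed``.
    """
    fractions = tuple(fractions)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    per = _participant_frame(inventory)
    n = len(per)
    n_train, n_corr, n_test = largest_remainder(n, fractions)
    rng = np.random.default_rng(seed)

    rare = set(rare_modalities)
    eligible = per[per["modalities"].map(lambda ms: bool(ms & rare))]
    common_pool = per.drop(eligible.index)

    assignment = pd.Series(index=per.index, dtype=object)
    if len(eligible) >= n_test:
        surplus = len(eligible) - n_test
        if surplus > n_corr:
            warnings.warn(
                "rare-modality carriers overflow the linear-correction target; "
                "its realised size exceeds the apportioned count")
        if len(common_pool) < n_train:
            raise ValueError(
                "too few common-modality participants to fill the training "
                "subdivision")
        pick = _stratified_allocate(
            eligible, {"test": n_test, "linear_correction": surplus}, rng)
        assignment.loc[pick.index] = pick
        # common pool covers training exactly; the remainder tops up the
        # linear-correction set, so totals stay n_train / n_corr / n_test
        # whenever surplus <= n_corr.
        pick2 = _stratified_allocate(
            common_pool, {"train": n_train,
                          "linear_correction": len(common_pool) - n_train}, rng)
        assignment.loc[pick2.index] = pick2
    else:
        shortfall = n_test - len(eligible)
        if len(eligible) > 0:  # rare modalities present but too few carriers
            warnings.warn(
                f"only {len(eligible)} rare-modality carriers for a test "
                f"target of {n_test}; drawing {shortfall} from the common pool")
        assignment.loc[eligible.index] = "test"
        pick = _stratified_allocate(
            common_pool,
            {"test": shortfall, "train": n_train,
             "linear_correction": len(common_pool) - shortfall - n_train},
            rng)
        assignment.loc[pick.index] = pick

    out = per[["participant_id", "n_scans"]].copy()
    out["subdivision"] = assignment.to_numpy()
    return out


def make_cv_folds(participants: pd.DataFrame, k: int = 3,
                  subsplit=(0.30, 0.70), seed: int = 0) -> pd.DataFrame:
    """Three-fold CV layout over training participants.

    Folds are near-equal at the participant level. In iteration ``j`` the
    other folds are ``cv_train``; fold ``j`` is subdivided ``subsplit`` into
    ``cv_bias`` (fitting the bias model) and ``cv_eval`` (evaluation /
    early-stopping monitor). Returns a long DataFrame with columns
    (iteration, participant_id, fold, role).
    """
    if abs(sum(subsplit) - 1.0) > 1e-9:
        raise ValueError("subsplit must sum to 1")
    per = participants.copy()
    n = len(per)
    if k < 2 or k > n:
        raise ValueError(f"need 2 <= k <= n participants (k={k}, n={n})")
    if "n_scans" not in per.columns:
        per["n_scans"] = 1
    rng = np.random.default_rng(seed)
    fold_sizes = largest_remainder(n, [1.0 / k] * k)
    fold_pick = _stratified_allocate(
        per, {str(j): fold_sizes[j - 1] for j in range(1, k + 1)}, rng)
    per["fold"] = fold_pick.astype(int)

    rows = []
    for j in range(1, k + 1):
        held = per[per["fold"] == j]
        n_bias, n_eval = largest_remainder(len(held), subsplit)
        pick = _stratified_allocate(
            held, {"cv_bias": n_bias, "cv_eval": n_eval}, rng)
        for pid, fold in zip(per["participant_id"], per["fold"]):
            if fold != j:
                rows.append((j, pid, fold, "cv_train"))
        for idx, role in pick.items():
            rows.append((j, held.loc[idx, "participant_id"], j, role))
    return pd.DataFrame(rows, columns=["iteration", "participant_id", "fold", "role"])
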