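"""Synthetic cohort, scan inventory, biased predictions and toy volumes.

This module generates data with the statistical structure the downstream
analysis assumes: a left-skewed, bounded age distribution; a multi-modality,
multi-scanner scan inventory with up to four repetitions per (participant,
modality); predictions carrying a linear regression-dilution bias plus
subject, scan and slice-level noise; and small template-like volumes with
labelled corruptions for the QC stage.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import (
    BiasSpec,
    CohortConfig,
    ConfigurationError,
    ScanInventorySpec,
    MAX_REPETITIONS,
)

__all__ = [
    "AgeMixture",
    "calibrate_age_mixture",
    "generate_cohort",
    "assign_scans",
    "generate_predictions",
    "make_template",
    "generate_volumes",
    "write_prediction_table",
    "read_prediction_table",
]

PREDICTION_COLUMNS = [
    "participant_id", "age_years", "modality", "scanner", "repetition",
    "brain_age_years",
]


# ---------------------------------------------------------------------------
# Age distribution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AgeMixture:
    """Two-component truncated normal mixture on a bounded age range."""

    weight: float          # mixing weight of the younger component
    mu1: float
    sigma1: float
    mu2: float
    sigma2: float
    lo: float
    hi: float

    def _components(self):
        out = []
        for mu, s in ((self.mu1, self.sigma1), (self.mu2, self.sigma2)):
            a, b = (self.lo - mu) / s, (self.hi - mu) / s
            out.append(stats.truncnorm(a, b, loc=mu, scale=s))
        return out

    def moments(self) -> tuple[float, float, float]:
        """Population (mean, median, sd)."""
        d1, d2 = self._components()
        w = self.weight
        m1, v1 = (float(x) for x in d1.stats(moments="mv"))
        m2, v2 = (float(x) for x in d2.stats(moments="mv"))
        mean = w * m1 + (1 - w) * m2
        var = w * (v1 + m1 ** 2) + (1 - w) * (v2 + m2 ** 2) - mean ** 2
        med = optimize.brentq(
            lambda x: w * d1.cdf(x) + (1 - w) * d2.cdf(x) - 0.5, self.lo, self.hi)
        return mean, float(med), float(np.sqrt(var))

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        d1, d2 = self._components()
        pick = rng.random(n) < self.weight
        ages = np.empty(n)
        ages[pick] = d1.rvs(size=int(pick.sum()), random_state=rng)
        ages[~pick] = d2.rvs(size=int((~pick).sum()), random_state=rng)
        return ages


@functools.lru_cache(maxsize=32)
def calibrate_age_mixture(lo: float, hi: float, mean: float, median: float,
                          sd: float) -> AgeMixture:
    """Solve mixture parameters so population mean/median/sd hit the targets.

    Nelder-Mead on the squared target error; raises if the optimum leaves a
    residual mismatch above 0.05 y on any target (infeasible configuration).
    """

    def objective(p):
        w, mu1, s1, mu2, s2 = p
        if not (0.01 < w < 0.99 and s1 > 1.0 and s2 > 1.0
                and lo - 40 < mu1 < hi + 40 and lo - 40 < mu2 < hi + 40):
            return 1e6
        m, md, s = AgeMixture(w, mu1, s1, mu2, s2, lo, hi).moments()
        return (m - mean) ** 2 + (md - median) ** 2 + (s - sd) ** 2

    span = hi - lo
    x0 = [0.3, lo + 0.2 * span, 0.12 * span, lo + 0.6 * span, 0.15 * span]
    res = optimize.minimize(objective, x0, method="Nelder-Mead",
                            options={"xatol": 1e-7, "fatol": 1e-12,
                                     "maxiter": 5000})
    mix = AgeMixture(*res.x, lo=lo, hi=hi)
    got = mix.moments()
    if max(abs(g - t) for g, t in zip(got, (mean, median, sd))) > 0.05:
        raise ConfigurationError(
            f"age targets (mean={mean}, median={median}, sd={sd}) infeasible "
            f"on range ({lo}, {hi}); best achievable {got}")
    return mix


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate participants with ids, ages and sex.

    Returns a DataFrame with columns (participant_id, age_years, sex),
    deterministic given ``config.seed``.
    """
    lo, hi = config.age_range
    mix = calibrate_age_mixture(lo, hi, config.age_mean_target,
                                config.age_median_target, config.age_sd_target)
    rng = np.random.default_rng(config.seed)
    ages = mix.rvs(config.n_participants, rng)
    sex = np.where(rng.random(config.n_participants) < config.sex_ratio, "F", "M")
    ids = [f"sub-{i:05d}" for i in range(config.n_participants)]
    return pd.DataFrame({"participant_id": ids, "age_years": ages, "sex": sex})


# ---------------------------------------------------------------------------
# Scan inventory
# ---------------------------------------------------------------------------

def _inclusion_probabilities(spec: ScanInventorySpec) -> dict[str, float]:
    """Per-participant modality inclusion probabilities matching the spec
    cell counts at the reference archive size."""
    probs = {}
    for mod, row in spec.modality_scanner_counts.items():
        reps = np.asarray(spec.repetition_counts.get(mod, (1.0,)), dtype=float)
        reps = reps / reps.sum()
        expected_reps = float(np.sum(reps * np.arange(1, len(reps) + 1)))
        n_carriers = sum(row.values()) / expected_reps
        probs[mod] = min(n_carriers / spec.reference_n_participants, 1.0)
    return probs


def assign_scans(participants: pd.DataFrame, spec: ScanInventorySpec,
                 seed: int) -> pd.DataFrame:
    """Build a scan inventory (rows without predictions).

    Each participant draws a modality set from the inclusion probabilities
    implied by the spec's cell counts; rare modalities are restricted to a
    ``rare_carrier_fraction`` subset of participants (who always receive at
    least one rare modality, exercising the held-out eligibility rule).
    Repetition counts per (participant, modality) follow the spec's
    per-modality law, capped at 4; the scanner is drawn once per
    (participant, modality) from the modality-conditional scanner frequencies.
    """
    if participants.empty:
        raise ValueError("participants must be non-empty")
    rng = np.random.default_rng(seed)
    probs = _inclusion_probabilities(spec)
    modalities = list(spec.modality_scanner_counts)
    rare = [m for m in spec.rare_modalities if m in modalities]
    common = [m for m in modalities if m not in rare]
    n = len(participants)

    carrier = rng.random(n) < spec.rare_carrier_fraction if rare else np.zeros(n, bool)
    # conditional inclusion probability for rare modalities among carriers
    rare_cond = {m: min(probs[m] / spec.rare_carrier_fraction, 1.0) for m in rare}
    rare_weights = np.array([probs[m] for m in rare], dtype=float) if rare else None

    rows: list[tuple] = []
    fallback = max(common or modalities, key=lambda m: probs[m])
    scanner_laws = {}
    for mod in modalities:
        row = spec.modality_scanner_counts[mod]
        names = [s for s, c in row.items() if c > 0]
        w = np.array([row[s] for s in names], dtype=float)
        scanner_laws[mod] = (names, w / w.sum())
    rep_laws = {}
    for mod in modalities:
        p = np.asarray(spec.repetition_counts.get(mod, (1.0,)), dtype=float)
        rep_laws[mod] = p / p.sum()

    for i, part in enumerate(participants.itertuples(index=False)):
        mods = [m for m in common if rng.random() < probs[m]]
        if carrier[i]:
            picked = [m for m in rare if rng.random() < rare_cond[m]]
            if not picked:  # carriers always hold at least one rare modality
                picked = [rare[rng.choice(len(rare), p=rare_weights / rare_weights.sum())]]
            mods += picked
        if not mods:
            mods = [fallback]
        for mod in mods:
            p = rep_laws[mod]
            n_rep = int(rng.choice(len(p), p=p)) + 1
            names, w = scanner_laws[mod]
            scanner = names[int(rng.choice(len(names), p=w))]
            for rep in range(1, min(n_rep, MAX_REPETITIONS) + 1):
                rows.append((part.participant_id, part.age_years, mod, scanner, rep))

    return pd.DataFrame(rows, columns=["participant_id", "age_years", "modality",
                                       "scanner", "repetition"])


# ---------------------------------------------------------------------------
# Biased predictions
# ---------------------------------------------------------------------------

def generate_predictions(inventory: pd.DataFrame, bias: BiasSpec, seed: int,
                         n_slices: int | None = None):
    """Attach biased brain-age predictions to a scan inventory.

    predicted = alpha + beta*age + modality_offset + scanner_offset
                + subject_effect + scan_noise (+ outlier shift for a random
    ``outlier_fraction`` of scans). With ``n_slices`` set, per-slice values are
    the scan value plus iid slice noise and the scan-level ``brain_age_years``
    is their median; a long-format slice table is returned alongside.
    """
    if inventory.empty:
        raise ValueError("inventory must be non-empty")
    rng = np.random.default_rng(seed)
    table = inventory.copy().reset_index(drop=True)
    age = table["age_years"].to_numpy()

    pids = table["participant_id"].to_numpy()
    uniq, inverse = np.unique(pids, return_inverse=True)
    subject_effect = rng.normal(0.0, bias.subject_effect_sd, size=len(uniq))[inverse]

    mod_off = table["modality"].map(lambda m: bias.modality_offsets.get(m, 0.0))
    scan_off = table["scanner"].map(lambda s: bias.scanner_offsets.get(s, 0.0))
    noise = rng.normal(0.0, bias.scan_noise_sd, size=len(table)) \
        if bias.scan_noise_sd > 0 else np.zeros(len(table))
    outlier = rng.random(len(table)) < bias.outlier_fraction
    shift = np.where(outlier, rng.normal(0.0, bias.outlier_shift_sd, len(table)), 0.0)

    scan_value = (bias.intercept_alpha + bias.slope_beta * age
                  + mod_off.to_numpy() + scan_off.to_numpy()
                  + subject_effect + noise + shift)
    table["is_outlier"] = outlier

    if n_slices is None:
        table["brain_age_years"] = scan_value
        return table

    slice_noise = rng.normal(0.0, bias.slice_noise_sd, size=(len(table), n_slices)) \
        if bias.slice_noise_sd > 0 else np.zeros((len(table), n_slices))
    per_slice = scan_value[:, None] + slice_noise
    table["brain_age_years"] = np.median(per_slice, axis=1)
    slices = pd.DataFrame({
        "scan_index": np.repeat(np.arange(len(table)), n_slices),
        "slice_index": np.tile(np.arange(n_slices), len(table)),
        "brain_age_years": per_slice.ravel(),
    })
    return table, slices


# ---------------------------------------------------------------------------
# Toy volumes for the QC stage
# ---------------------------------------------------------------------------

def make_template(shape: tuple[int, int, int] = (48, 48, 48)) -> np.ndarray:
    """Smooth brain-like intensity pattern on the given grid, range [0, 255].

    An ellipsoidal soft mask with a radial intensity gradient; purely a QC
    fixture, no attempt at MR contrast realism.
    """
    if any(s < 8 for s in shape):
        raise ValueError(f"shape {shape} too small for a template")
    grids = np.meshgrid(*[np.linspace(-1.0, 1.0, s) for s in shape], indexing="ij")
    r2 = sum((g / f) ** 2 for g, f in zip(grids, (0.9, 0.75, 0.9)))
    body = np.clip(1.0 - r2, 0.0, None)
    # inner bright shell emulating tissue-contrast structure
    vol = 255.0 * (body ** 0.7) * (0.6 + 0.4 * np.cos(3.0 * np.sqrt(r2)))
    return np.clip(vol, 0.0, 255.0)


def lps_affine(shape: tuple[int, int, int], spacing: float = 1.0) -> np.ndarray:
    """1-mm-style affine with the grid centred at world origin (LPS storage)."""
    aff = np.diag([-spacing, -spacing, spacing, 1.0])
    aff[:3, 3] = [spacing * (shape[0] // 2), spacing * (shape[1] // 2),
                  -spacing * (shape[2] // 2)]
    return aff


def generate_volumes(inventory: pd.DataFrame, seed: int,
                     shape: tuple[int, int, int] = (48, 48, 48),
                     n_corrupted: int = 0, clean_noise_sd: float = 6.0,
                     modes: tuple[str, ...] = ("heavy_noise", "blanked",
                                               "misplaced")):
    """Generate toy volumes for a subset of scans, with labelled corruptions.

    Returns ``(volumes, manifest)``: a list of nibabel images aligned with the
    inventory rows and a DataFrame manifest carrying the ground-truth
    ``corrupted`` flag and the corruption mode. Corrupted volumes get heavy
    noise, a blanked half, or a spatial misplacement of the template pattern.
    """
    import nibabel as nib

    if n_corrupted > len(inventory):
        raise ValueError("n_corrupted exceeds the number of scans")
    rng = np.random.default_rng(seed)
    template = make_template(shape)
    affine = lps_affine(shape)
    n = len(inventory)
    corrupted_idx = set(rng.choice(n, size=n_corrupted, replace=False).tolist())

    volumes, records = [], []
    for i in range(n):
        gain = 1.0 + 0.05 * rng.standard_normal()
        vol = gain * template + rng.normal(0.0, clean_noise_sd, shape)
        mode = ""
        if i in corrupted_idx:
            mode = modes[int(rng.integers(len(modes)))]
            if mode == "heavy_noise":
                vol = rng.uniform(0.0, 255.0, shape)
            elif mode == "blanked":
                vol[: shape[0] // 2] = 0.0  # half the acquisition lost
            else:  # misplaced: roll the pattern by a third of the grid
                vol = np.roll(vol, shift=shape[0] // 3, axis=0)
                vol += rng.normal(0.0, 20.0, shape)
        vol = np.clip(vol, 0.0, 255.0)
        volumes.append(nib.Nifti1Image(vol.astype(np.float32), affine))
        records.append({"corrupted": i in corrupted_idx, "mode": mode})

    manifest = inventory.reset_index(drop=True).copy()
    manifest[["corrupted", "mode"]] = pd.DataFrame(records)
    return volumes, manifest


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------

def write_prediction_table(table: pd.DataFrame, path) -> None:
    cols = [c for c in PREDICTION_COLUMNS if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    table[cols].to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_prediction_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = set(PREDICTION_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"prediction table missing columns: {sorted(missing)}")
    return table
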