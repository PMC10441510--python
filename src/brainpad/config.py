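"""Configuration dataclasses for the synthetic cohort and the pipeline.

The defaults encode the study conditions the pipeline is designed around: a
clinical MRI archive of 1,540 patients scanned on 8 scanner models across 7
modalities, with a left-skewed age distribution (range 15-95 y, mean 53.5,
median 56, sd 18) and a regression-dilution bias on the predicted brain ages
(intercept 15.2 y, slope 0.7).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

SCANNERS: tuple[str, ...] = (
    "Aera", "Avanto", "Prisma", "Sola", "SignaHDxt", "Skyra", "Titan3T", "Verio",
)

#: Modalities with enough scans to train on.
COMMON_MODALITIES: tuple[str, ...] = ("MPRAGE", "T1w", "T2w", "T2wFLAIR")
#: Sparse modalities reserved for held-out testing.
RARE_MODALITIES: tuple[str, ...] = ("T1wFLAIR", "T2wGRE", "IR")
MODALITIES: tuple[str, ...] = COMMON_MODALITIES + RARE_MODALITIES

#: Scans per (modality, scanner) cell in the emulated clinical archive
#: (1,540 participants, 6,224 scans that passed QC).
DEFAULT_MODALITY_SCANNER_COUNTS: dict[str, dict[str, int]] = {
    "MPRAGE":   {"Aera": 148, "Avanto": 182, "Prisma": 162, "Sola": 45,
                 "SignaHDxt": 73, "Skyra": 25, "Titan3T": 30, "Verio": 182},
    "T1w":      {"Aera": 268, "Avanto": 518, "Prisma": 240, "Sola": 38,
                 "SignaHDxt": 154, "Skyra": 32, "Titan3T": 115, "Verio": 438},
    "T2w":      {"Aera": 394, "Avanto": 565, "Prisma": 301, "Sola": 49,
                 "SignaHDxt": 271, "Skyra": 49, "Titan3T": 128, "Verio": 465},
    "T1wFLAIR": {"Aera": 2, "Avanto": 8, "Prisma": 2, "Sola": 0,
                 "SignaHDxt": 73, "Skyra": 1, "Titan3T": 0, "Verio": 4},
    "T2wFLAIR": {"Aera": 234, "Avanto": 120, "Prisma": 227, "Sola": 48,
                 "SignaHDxt": 158, "Skyra": 40, "Titan3T": 82, "Verio": 108},
    "T2wGRE":   {"Aera": 0, "Avanto": 0, "Prisma": 0, "Sola": 0,
                 "SignaHDxt": 151, "Skyra": 0, "Titan3T": 0, "Verio": 0},
    "IR":       {"Aera": 4, "Avanto": 12, "Prisma": 36, "Sola": 1,
                 "SignaHDxt": 0, "Skyra": 15, "Titan3T": 0, "Verio": 26},
}

#: Participants having 1, 2, 3 or 4 repetitions of each modality in the
#: emulated archive; normalised to probabilities at generation time.
DEFAULT_REPETITION_COUNTS: dict[str, tuple[int, int, int, int]] = {
    "MPRAGE": (833, 7, 0, 0),
    "T1w": (680, 541, 11, 2),
    "T2w": (606, 763, 26, 3),
    "T1wFLAIR": (50, 20, 0, 0),
    "T2wFLAIR": (981, 18, 0, 0),
    "T2wGRE": (151, 0, 0, 0),
    "IR": (32, 31, 0, 0),
}

#: Archive scale the cell counts refer to.
REFERENCE_N_PARTICIPANTS = 1540

MAX_REPETITIONS = 4

#: Template grid the prediction slices are defined on (1 mm isotropic, LPS).
TEMPLATE_SHAPE: tuple[int, int, int] = (218, 182, 218)
N_PREDICTION_SLICES = 80


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass(frozen=True)
class CohortConfig:
    """Demographics of the synthetic cohort.

    Ages are drawn from a two-component truncated normal mixture calibrated so
    the population mean / median / sd match the targets inside ``age_range``;
    the default targets give a left-skewed distribution (mean < median).
    """

    n_participants: int = 1540
    age_range: tuple[float, float] = (15.0, 95.0)
    age_mean_target: float = 53.5
    age_median_target: float = 56.0
    age_sd_target: float = 18.0
    sex_ratio: float = 1039 / 1540  # proportion female
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.age_range
        if self.n_participants <= 0:
            raise ConfigurationError("n_participants must be positive")
        if not lo < hi:
            raise ConfigurationError("age_range must satisfy low < high")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ConfigurationError("sex_ratio must lie in [0, 1]")
        for t in (self.age_mean_target, self.age_median_target):
            if not lo < t < hi:
                raise ConfigurationError(f"target {t} outside age_range {self.age_range}")
        if not 0 < self.age_sd_target < (hi - lo) / 2:
            # half-range is the sd supremum for any distribution on [lo, hi]
            raise ConfigurationError("age_sd_target infeasible for age_range")


@dataclass(frozen=True)
class ScanInventorySpec:
    """Expected scan counts per (modality, scanner) cell plus repetition law.

    ``repetition_counts`` map each modality to the relative frequency of a
    participant having 1..4 repetitions of it. ``rare_carrier_fraction`` is the
    fraction of participants allowed to carry the rare (test-only) modalities,
    which drives the held-out-set eligibility rule downstream.
    """

    modality_scanner_counts: Mapping[str, Mapping[str, int]] = field(
        default_factory=lambda: DEFAULT_MODALITY_SCANNER_COUNTS)
    repetition_counts: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: DEFAULT_REPETITION_COUNTS)
    rare_modalities: tuple[str, ...] = RARE_MODALITIES
    rare_carrier_fraction: float = 0.145
    reference_n_participants: int = REFERENCE_N_PARTICIPANTS
    max_repetitions: int = MAX_REPETITIONS

    def __post_init__(self) -> None:
        if not self.modality_scanner_counts:
            raise ConfigurationError("modality_scanner_counts must be non-empty")
        for mod, row in self.modality_scanner_counts.items():
            if any(c < 0 for c in row.values()):
                raise ConfigurationError(f"negative count for modality {mod!r}")
            if sum(row.values()) == 0:
                raise ConfigurationError(f"modality {mod!r} has zero total count")
        for mod, probs in self.repetition_counts.items():
            if len(probs) > self.max_repetitions:
                raise ConfigurationError(
                    f"repetition law for {mod!r} exceeds max_repetitions")
            if any(p < 0 for p in probs) or sum(probs) <= 0:
                raise ConfigurationError(f"invalid repetition law for {mod!r}")
        if not 0.0 < self.rare_carrier_fraction <= 1.0:
            raise ConfigurationError("rare_carrier_fraction must lie in (0, 1]")
        if self.max_repetitions != MAX_REPETITIONS:
            raise ConfigurationError(f"max_repetitions is fixed at {MAX_REPETITIONS}")

    @property
    def modalities(self) -> tuple[str, ...]:
        return tuple(self.modality_scanner_counts)


@dataclass(frozen=True)
class BiasSpec:
    """Generating law for the biased predictions.

    predicted = intercept + slope * age + modality_offset + scanner_offset
                + subject_effect + scan_noise, with an ``outlier_fraction`` of
    scans additionally shifted by N(0, outlier_shift_sd) to emulate grossly
    corrupted inputs. Per-slice outputs add iid N(0, slice_noise_sd) around the
    scan-level value.
    """

    intercept_alpha: float = 15.2
    slope_beta: float = 0.7
    modality_offsets: Mapping[str, float] = field(default_factory=dict)
    scanner_offsets: Mapping[str, float] = field(default_factory=dict)
    subject_effect_sd: float = 3.0
    scan_noise_sd: float = 5.0
    slice_noise_sd: float = 2.0
    outlier_fraction: float = 0.02
    outlier_shift_sd: float = 15.0

    def __post_init__(self) -> None:
        for name in ("subject_effect_sd", "scan_noise_sd", "slice_noise_sd",
                     "outlier_shift_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0.0 <= self.outlier_fraction < 0.5:
            raise ConfigurationError("outlier_fraction must lie in [0, 0.5)")


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end pipeline settings (simulate -> QC -> split -> correct -> evaluate)."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    inventory: ScanInventorySpec = field(default_factory=ScanInventorySpec)
    bias: BiasSpec = field(default_factory=BiasSpec)
    split_fractions: tuple[float, float, float] = (0.77, 0.085, 0.145)
    final_fit_holdout_fraction: float = 0.10
    cv_folds: int = 3
    cv_subsplit: tuple[float, float] = (0.30, 0.70)
    correction_candidates: tuple[str, ...] = (
        "age", "age*modality", "age*scanner", "age*modality*scanner")
    n_boot_factor: int = 10_000
    ci_level: float = 0.95
    reliability_min_items: int = 3
    reliability_max_missing: float = 0.95
    qc_enabled: bool = True
    qc_n_volumes: int = 18
    qc_n_corrupted: int = 3
    qc_volume_shape: tuple[int, int, int] = (48, 48, 48)
    group_model_path: str = "fixed_and_random"
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ConfigurationError("split_fractions must sum to 1")
        if abs(sum(self.cv_subsplit) - 1.0) > 1e-9:
            raise ConfigurationError("cv_subsplit must sum to 1")
        if self.cv_folds < 2:
            raise ConfigurationError("cv_folds must be >= 2")
        if not 0 < self.ci_level < 1:
            raise ConfigurationError("ci_level must lie in (0, 1)")

    @classmethod
    def from_json(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a config from a JSON file; keyword overrides win."""
        raw = json.loads(Path(path).read_text())
        raw.update(overrides)
        kwargs = {}
        for key, value in raw.items():
            if key == "cohort":
                kwargs[key] = CohortConfig(**_tuplify(value, ("age_range",)))
            elif key == "inventory":
                kwargs[key] = ScanInventorySpec(**_tuplify(value, ("rare_modalities",)))
            elif key == "bias":
                kwargs[key] = BiasSpec(**value)
            elif key in ("split_fractions", "cv_subsplit", "correction_candidates",
                         "qc_volume_shape"):
                kwargs[key] = tuple(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=list))


def _tuplify(d: dict, keys: Sequence[str]) -> dict:
    return {k: (tuple(v) if k in keys else v) for k, v in d.items()}
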