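import numpy as np
import pandas as pd
import pytest

from brainpad import BiasSpec, CohortConfig, ScanInventorySpec, cohort


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    return cohort.generate_cohort(CohortConfig(n_participants=300, seed=7))


@pytest.fixture(scope="session")
def inventory(small_cohort) -> pd.DataFrame:
    return cohort.assign_scans(small_cohort, ScanInventorySpec(), seed=11)


@pytest.fixture(scope="session")
def pred_table(inventory) -> pd.DataFrame:
    return cohort.generate_predictions(inventory, BiasSpec(), seed=13)


def make_table(participants, ages, modalities, repetitions, predicted,
               scanner="Avanto") -> pd.DataFrame:
    """Hand-constructed prediction table for exact-arithmetic tests."""
    n = len(participants)
    return pd.DataFrame({
        "participant_id": participants,
        "age_years": np.asarray(ages, dtype=float),
        "modality": modalities if not isinstance(modalities, str)
        else [modalities] * n,
        "scanner": scanner if not isinstance(scanner, str)
        else [scanner] * n,
        "repetition": repetitions,
        "brain_age_years": np.asarray(predicted, dtype=float),
    })
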