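import numpy as np
import pandas as pd
import pytest

from hrvstress import (
    PairedDataset,
    SyntheticParams,
    extract_all_features,
    generate_cohort,
    to_nn,
)
from hrvstress.features import FEATURE_NAMES
from hrvstress.pipeline import StudyConfig, extract_features


def make_rr_like(rng: np.random.Generator, n: int, mean: float = 0.8,
                 sd: float = 0.05) -> np.ndarray:
    """Positive RR-like random series."""
    return np.clip(mean + sd * rng.standard_normal(n), 0.3, None)


def gaussian_feature_frame(rng: np.random.Generator, n_subjects: int,
                           shift: dict[str, float] | None = None) -> pd.DataFrame:
    """Feature table with standard-normal features; `shift` moves the
    stress-session mean of the named features."""
    shift = shift or {}
    rows = []
    for s in range(n_subjects):
        for session in ("rest", "stress"):
            row = {"subject_id": f"S{s:03d}", "session": session}
            for name in FEATURE_NAMES:
                value = rng.standard_normal()
                if session == "stress":
                    value += shift.get(name, 0.0)
                row[name] = value
            rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_cohort_features() -> pd.DataFrame:
    """Extracted features for a small synthetic cohort (shared, read-only)."""
    params = SyntheticParams(n_subjects=8, seed=11)
    nns = [to_nn(rec) for rec in generate_cohort(params)]
    return extract_features(nns, StudyConfig(synthetic=params))


@pytest.fixture(scope="session")
def small_cohort_dataset(small_cohort_features) -> PairedDataset:
    return PairedDataset(small_cohort_features)
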