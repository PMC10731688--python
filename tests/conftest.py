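"""Shared fixtures: programmatic cohort builders and seeded synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from screeneval.cohort import COHORT_COLUMNS, validate_cohort
from screeneval.synthetic import GeneratorParams, generate


def make_cohort(
    reader1,
    reader2,
    *,
    arbitration=None,
    ai_score=None,
    dx_offset_days=None,
    next_screen_offset_days=None,
    subtype=None,
    invasive=None,
    extra: dict | None = None,
) -> pd.DataFrame:
    """Build a minimal validated cohort frame from per-exam arrays.

    Unspecified optional fields are absent; demographics are filled with
    constants so only the decision/outcome structure matters.
    """
    n = len(reader1)
    df = pd.DataFrame({c: [None] * n for c in COHORT_COLUMNS})
    df["exam_id"] = [f"E{i:07d}" for i in range(n)]
    df["woman_id"] = [f"W{i:07d}" for i in range(n)]
    df["site"] = "Odense"
    df["age_years"] = 59.3
    df["screen_date"] = "2016-01-01"
    df["reader1"] = np.asarray(reader1, dtype=np.int8)
    df["reader2"] = np.asarray(reader2, dtype=np.int8)
    df["ai_score"] = 0.0 if ai_score is None else np.asarray(ai_score, dtype=float)
    if arbitration is not None:
        df["arbitration"] = pd.array(arbitration, dtype="Int8")
    if dx_offset_days is not None:
        df["dx_offset_days"] = pd.array(dx_offset_days, dtype="Int64")
    if next_screen_offset_days is not None:
        df["next_screen_offset_days"] = pd.array(next_screen_offset_days, dtype="Int64")
    if subtype is not None:
        df["subtype"] = subtype
    if invasive is not None:
        df["invasive"] = pd.array(invasive, dtype="boolean")
    for key, val in (extra or {}).items():
        df[key] = val
    return validate_cohort(df)


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """20k-exam synthetic cohort at the default stated world (seed 7)."""
    return generate(GeneratorParams(n_exams=20_000, seed=7))


@pytest.fixture(scope="session")
def default_cohort_200k() -> pd.DataFrame:
    """Full-size default synthetic cohort (200k exams, seed 11)."""
    return generate(GeneratorParams(n_exams=200_000, seed=11))
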