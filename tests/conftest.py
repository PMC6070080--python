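import numpy as np
import pandas as pd
import pytest

from rdipw import SimConfig, expand_person_periods, generate_cohort


def make_cohort_frame(subjects):
    """Build a minimal cohort DataFrame from per-subject dicts.

    Fills the covariates the expansion carries along with neutral values so
    tests can focus on timing fields.
    """
    defaults = dict(
        baseline_cd4=150.0,
        age=30.0,
        sex="female",
        education="8-12",
        wealth_quintile=3.0,
        distance_km=2.0,
        residence="rural",
        entry_time=0,
        art_init_time=np.nan,
        event_time=np.nan,
    )
    rows = []
    for i, s in enumerate(subjects):
        row = dict(defaults)
        row["subject_id"] = i
        row.update(s)
        row.setdefault("lab_times", "0")
        row.setdefault("lab_cd4", str(row["baseline_cd4"]))
        rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def default_cohort():
    """Mid-sized cohort under generator defaults (true HR 0.5, fuzzy
    compliance, confounding by indication)."""
    cohort, truth = generate_cohort(SimConfig(n_subjects=3000, seed=42))
    return cohort, truth


@pytest.fixture(scope="session")
def default_pp(default_cohort):
    cohort, _ = default_cohort
    return expand_person_periods(cohort)
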