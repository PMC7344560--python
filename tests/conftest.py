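"""Shared fixtures: small simulated cohorts and synthetic feature tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import gaitstate as gs
from gaitstate.signal_io import FEATURE_NAMES


@pytest.fixture(scope="session")
def small_cohort():
    """Six-subject separable cohort at reduced duration (fast fixture)."""
    from dataclasses import replace

    on = replace(gs.ON_DEFAULT, duration_s=60.0)
    off = replace(gs.OFF_DEFAULT, duration_s=60.0)
    return gs.simulate_cohort(6, on, off, seed=11)


@pytest.fixture(scope="session")
def small_table(small_cohort):
    cohort, _ = small_cohort
    return gs.featurize_cohort(cohort)


@pytest.fixture(scope="session")
def reference_table():
    """The published per-subject confusion/count rows (without the Total row)."""
    return gs.load_reference_subject_table()


def synthetic_feature_table(
    n_subjects: int = 6, windows_per_course: int = 5, seed: int = 0, informative: bool = True
) -> pd.DataFrame:
    """A random feature table with the full 32-column schema.

    With ``informative=True`` the first feature column alone separates the
    labels; all other columns are pure noise.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        sid = f"T{i:02d}"
        for label in ("on", "off"):
            for w in range(windows_per_course):
                row = {
                    "subject_id": sid,
                    "course_id": f"{sid}_{label}",
                    "window_index": w,
                    "label": label,
                }
                values = rng.normal(0, 1, len(FEATURE_NAMES))
                if informative:
                    values[0] = (1.0 if label == "on" else -1.0) + rng.normal(0, 0.05)
                row.update(dict(zip(FEATURE_NAMES, values)))
                rows.append(row)
    return pd.DataFrame(rows)
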