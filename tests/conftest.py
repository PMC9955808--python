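"""Shared fixtures: synthetic sessions and small labelled feature tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from masgrade.features import FEATURE_NAMES
from masgrade.io import MAS_LABELS
from masgrade.pipeline import cohort_feature_table
from masgrade.synthetic import generate_cohort, generate_session


@pytest.fixture(scope="session")
def clean_sessions():
    """One noise-free session per MAS grade, with ground truth."""
    return {mas: generate_session(mas, seed=11, noise_scale=0.0) for mas in MAS_LABELS}


@pytest.fixture(scope="session")
def noisy_cohort_features():
    """Feature table of a 12-session-per-grade cohort at default noise."""
    recordings, labels, truths = generate_cohort(12, seed=303)
    return cohort_feature_table(recordings)


def make_feature_table(
    class_counts: dict[str, int], seed: int = 0, separated: bool = False
) -> pd.DataFrame:
    """Random labelled feature table with the requested per-grade counts.

    ``separated=True`` shifts each grade's feature cloud far apart so the
    classes are trivially separable.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for ci, (label, n) in enumerate(class_counts.items()):
        for i in range(n):
            values = rng.normal(size=len(FEATURE_NAMES))
            if separated:
                values = values * 0.05 + 10.0 * ci
            row = {
                "subject_id": f"S{label}{i}",
                "trial_id": "T1",
                "stretch_index": i,
                "speed": "fast",
                "mas_label": label,
            }
            row.update(dict(zip(FEATURE_NAMES, values)))
            rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture
def feature_table_factory():
    return make_feature_table
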