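import numpy as np
import pandas as pd
import pytest

from voicestate import SyntheticConfig, generate_cohort
from voicestate.modeling import clean_features


@pytest.fixture(scope="session")
def small_cohort():
    """A small three-group cohort with BD self-reports."""
    cfg = SyntheticConfig(
        n_bd=6,
        n_ur=2,
        n_hc=4,
        days_per_participant=(8, 12),
        calls_per_day=1.5,
        n_features=8,
        seed=11,
        missing_report_prob=0.2,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def bd_state_cohort():
    """A BD-only cohort with enough depression days for state contrasts."""
    cfg = SyntheticConfig(
        n_bd=8,
        n_ur=0,
        n_hc=0,
        days_per_participant=(40, 60),
        calls_per_day=1.2,
        n_features=12,
        state_effect=0.8,
        fingerprint_sd=1.0,
        missing_report_prob=0.1,
        state_prevalence={
            "mania": 0.03,
            "depression": 0.30,
            "increased_activity": 0.29,
            "decreased_activity": 0.23,
            "insomnia": 0.19,
        },
        seed=21,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def toy_entries():
    """Hand-built feature table: 2 BD participants (5 calls) + 1 HC (3)."""
    rows = []
    for pid, n in (("A", 3), ("B", 2), ("C", 3)):
        for i in range(n):
            rows.append(
                {
                    "participant_id": pid,
                    "timestamp": f"2019-01-0{i + 1}T10:00:00",
                    "f0001": float(i),
                    "f0002": float(i) * 2 + (0.5 if pid == "C" else 0.0),
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture()
def toy_roster():
    return pd.DataFrame(
        {"participant_id": ["A", "B", "C"], "group": ["BD", "BD", "HC"]}
    )


def brute_force_auc(scores, labels):
    """All-pairs Mann-Whitney AUC oracle: ties count one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


@pytest.fixture(scope="session")
def cleaned(small_cohort):
    return clean_features(small_cohort.entries)
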