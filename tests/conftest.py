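"""Shared fixtures: small random logs and the trained benchmark models.

The 2,000-patient synthetic benchmark and both trained strategies are
session-scoped because several tests (predictive recovery, filtering
behaviour, explanation recovery) probe the same study conditions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from xae.autoencoder import PathwayAutoencoder
from xae.eventlog import (
    apply_label_set,
    enrich_with_hierarchy,
    filter_infrequent,
    read_event_log,
    read_hierarchy,
    split_train_test,
)
from xae.synthdata import (
    SimulationConfig,
    generate_event_log,
    generate_hierarchy,
    worked_example,
)
from xae.tensorize import PathwayTensorizer


def random_event_rows(rng: np.random.Generator, n_rows: int = 50, n_patients: int = 5,
                      codes=("C1", "C2", "C3", "C4")) -> pd.DataFrame:
    """Raw (unmerged) event rows for group-by oracle tests."""
    return pd.DataFrame(
        {
            "patient_id": rng.choice([f"P{i}" for i in range(n_patients)], n_rows),
            "date": rng.choice(
                pd.date_range("2020-01-01", periods=20).strftime("%Y-%m-%d"), n_rows
            ),
            "code": rng.choice(list(codes), n_rows),
            "system": "DIAG",
        }
    )


def outcomes_for(rows: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    patients = sorted(rows["patient_id"].unique())
    return pd.DataFrame(
        {
            "patient_id": patients,
            "outcome": rng.integers(0, 2, len(patients)),
            "index_date": "2020-06-01",
        }
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture()
def worked_example_log(tmp_path):
    """The packaged single-patient worked example, parsed and enriched."""
    events, hierarchy, outcomes = worked_example()
    events.to_csv(tmp_path / "events.csv", index=False)
    hierarchy.to_csv(tmp_path / "hierarchy.csv", index=False)
    outcomes.to_csv(tmp_path / "outcomes.csv", index=False)
    log = read_event_log(tmp_path / "events.csv", tmp_path / "outcomes.csv")
    h = read_hierarchy(tmp_path / "hierarchy.csv")
    return enrich_with_hierarchy(log, h)


@pytest.fixture(scope="session")
def benchmark():
    """The 2,000-patient benchmark, prepared end-to-end (seed fixed)."""
    cfg = SimulationConfig(seed=11)
    log, truth = generate_event_log(cfg)
    enriched = enrich_with_hierarchy(log, generate_hierarchy(cfg))
    train_log, test_log = split_train_test(enriched, 0.2, seed=1)
    train_log, labels = filter_infrequent(train_log, 10)
    test_log = apply_label_set(test_log, labels)
    tensorizer = PathwayTensorizer(cfg.window_spec).fit(train_log)
    return {
        "config": cfg,
        "truth": truth,
        "train": tensorizer.transform(train_log),
        "test": tensorizer.transform(test_log),
        "labels": labels,
    }


@pytest.fixture(scope="session")
def filter_ae(benchmark) -> PathwayAutoencoder:
    """Plain AE trained with the filter objective on the benchmark."""
    model = PathwayAutoencoder(alpha="F", architecture="AE", random_state=1)
    return model.fit(benchmark["train"].values, benchmark["train"].classes)


@pytest.fixture(scope="session")
def inverse_vae(benchmark) -> PathwayAutoencoder:
    """VAE trained with the inverse objective on the benchmark."""
    model = PathwayAutoencoder(alpha="I", architecture="VAE", random_state=1)
    return model.fit(benchmark["train"].values, benchmark["train"].classes)
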