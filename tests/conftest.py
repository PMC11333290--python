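import numpy as np
import pandas as pd
import pytest

import clinclock as cc


@pytest.fixture(scope="session")
def signal_cohort():
    """Mid-size cohort with one mortality-carrying latent factor (effect 0.5)."""
    cfg = cc.SyntheticConfig(n_subjects=2000, n_features=12, n_latent=2,
                             latent_effects=(0.5, 0.0), age_coupling=(0.4, 0.0),
                             seed=101)
    cohort, truth = cc.generate_cohort(cfg)
    return cohort, truth


@pytest.fixture(scope="session")
def trained_clock(signal_cohort):
    """Full-PC clock trained on the signal cohort."""
    cohort, _ = signal_cohort
    norm = cc.fit_normalization(cohort)
    pc_model = cc.fit_svd(cohort, norm)
    cc.select_components(pc_model, 0.99)
    null = cc.fit_null_model(cohort)
    clock = cc.fit_pc_cox(cohort, pc_model, null)
    return clock


@pytest.fixture()
def toy_cohort():
    """Four-subject, three-feature cohort for contract tests."""
    ids = pd.Index([f"s{i}" for i in range(4)], name="subject_id")
    meta = pd.DataFrame({
        "sex": ["male", "female", "male", "female"],
        "chron_age": [50.0, 60.0, 70.0, 80.0],
        "followup_time": [5.0, 10.0, 2.0, 20.0],
        "event": [1, 0, 1, 0],
    }, index=ids)
    X = pd.DataFrame({
        "alpha": [1.0, 2.0, 3.0, 4.0],
        "beta": [10.0, 20.0, 30.0, 40.0],
        "gamma": [0.5, 0.25, 0.75, 1.0],
    }, index=ids)
    return cc.CohortTable(meta=meta, X=X)
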