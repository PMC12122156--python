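"""Shared fixtures.

The expensive artefacts — a trained VAD, a 200-patient effect-carrying
cohort with its full feature table, and a batch of null (no-effect) cohort
evaluations — are session-scoped so every test that needs them shares one
computation.
"""

import numpy as np
import pandas as pd
import pytest

from voicedep import (
    CohortSpec,
    TrainConfig,
    cohort_feature_table,
    generate_cohort,
    run_cv_experiment,
    train_vad,
)


@pytest.fixture(scope="session")
def vad_model():
    return train_vad()


@pytest.fixture(scope="session")
def women200(vad_model):
    """200 women, depression effect size 1, default recording conditions:
    the main cohort for separation / classification / attribution checks."""
    spec = CohortSpec(
        n_patients=200, female_fraction=1.0, prevalence=0.625,
        effect_size=1.0, seed=42,
    )
    records, cohort = generate_cohort(spec)
    features = cohort_feature_table(records, spec, vad_model=vad_model)
    return spec, records, cohort, features


@pytest.fixture(scope="session")
def women200_report(women200):
    """Cross-validated evaluation of the main cohort (k = 3, tau 1-4)."""
    _, _, cohort, features = women200
    config = TrainConfig(ks=(3,), taus=(1, 2, 3, 4), seed=7)
    return run_cv_experiment(features, cohort, config)


@pytest.fixture(scope="session")
def null_cohort_reports(vad_model):
    """Ten independent no-effect cohorts evaluated end to end: the chance
    calibration sample (24 women each, 50% prevalence, effect size 0)."""
    rows = []
    for seed in range(10):
        spec = CohortSpec(
            n_patients=24, female_fraction=1.0, prevalence=0.5,
            effect_size=0.0, seed=100 + seed,
        )
        records, cohort = generate_cohort(spec)
        features = cohort_feature_table(records, spec, vad_model=vad_model)
        rep = run_cv_experiment(
            features, cohort, TrainConfig(ks=(3,), taus=(2,), seed=seed)
        )
        rows.append(rep.iloc[0])
    return pd.DataFrame(rows).reset_index(drop=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
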