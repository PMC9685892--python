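"""Shared fixtures: synthetic cohorts at the study scale and small matrices."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ihtminer import IndicatorMatrix, default_config, generate_cohort


def random_matrix(
    n_patients: int, n_items: int, seed: int, prevalence: float = 0.3, death_rate: float = 0.2
) -> IndicatorMatrix:
    """Unstructured random indicator matrix for oracle-equivalence tests."""
    rng = np.random.default_rng(seed)
    items = pd.DataFrame(
        (rng.random((n_patients, n_items)) < prevalence).astype(np.int8),
        index=pd.Index([f"P{i:05d}" for i in range(n_patients)], name="patient_id"),
        columns=[f"dx_Item.{chr(65 + j)}" for j in range(n_items)],
    )
    return IndicatorMatrix(
        items=items,
        died=(rng.random(n_patients) < death_rate).astype(np.int8),
        age=rng.integers(21, 91, n_patients),
        sex=rng.choice(["Male", "Female"], n_patients),
        race=rng.choice(["White", "Black", "Other"], n_patients),
    )


@pytest.fixture(scope="session")
def recovery_simulation():
    """100-replicate logistic parameter-recovery run at n = 5,000.

    Returns per-coefficient counts of replicates whose estimate fell
    within 2 Wald standard errors of the truth. Session-scoped: the
    same run backs both the unit-level and end-to-end coverage checks.
    """
    from ihtminer import fit_logistic

    true = {"intercept": -2.0, "x1": 0.7, "x2": -0.4, "x3": 0.5}
    hits = {k: 0 for k in true}
    for rep in range(100):
        rng = np.random.default_rng(1000 + rep)
        n = 5000
        X = pd.DataFrame(
            {
                "x1": rng.standard_normal(n),
                "x2": rng.standard_normal(n),
                "x3": rng.integers(0, 2, n).astype(float),
            }
        )
        eta = (
            true["intercept"]
            + true["x1"] * X["x1"]
            + true["x2"] * X["x2"]
            + true["x3"] * X["x3"]
        )
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        fit = fit_logistic(X, y)
        for name, value in true.items():
            if abs(fit.params[name] - value) <= 2 * fit.bse[name]:
                hits[name] += 1
    return hits


@pytest.fixture(scope="session")
def small_config():
    return default_config(n_patients=2500, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def study_scale_config():
    """Default conditions at n = 50,000 for Monte-Carlo checks."""
    return default_config(n_patients=50_000, seed=1)


@pytest.fixture(scope="session")
def study_scale_cohort(study_scale_config):
    return generate_cohort(study_scale_config)


@pytest.fixture(scope="session")
def study_scale_matrix(study_scale_cohort):
    return study_scale_cohort.to_indicator_matrix()


@pytest.fixture(scope="session")
def no_confounding_matrix():
    """50k cohort whose demographics do not affect mortality."""
    cfg = default_config(
        n_patients=50_000,
        seed=2,
        covariate_effects={"age_per_decade": 0.0, "sex": {}, "race": {}},
    )
    return generate_cohort(cfg).to_indicator_matrix()
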