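import numpy as np
import pandas as pd
import pytest

from naccsubtypes import synthetic_data as sdata


@pytest.fixture(scope="session")
def right_cohort():
    """89-subject cohort with right-ROI subtypes assigned (fixed seeds)."""
    cohort = sdata.generate_cohort(45, 44, seed=11)
    return sdata.assign_subtypes(cohort, sdata.DEFAULT_RIGHT_SPECS, seed=12)


@pytest.fixture(scope="session")
def right_patterns(right_cohort):
    return sdata.generate_response_patterns(
        right_cohort, sdata.DEFAULT_RIGHT_SPECS, noise_sd=0.08, seed=13
    )


@pytest.fixture(scope="session")
def right_matrix(right_patterns):
    X, subjects = sdata.patterns_to_matrix(right_patterns, phase="anticipation")
    return X, subjects


@pytest.fixture(scope="session")
def right_long(right_patterns, right_cohort):
    cdf = sdata.cohort_to_frame(right_cohort)
    return (
        right_patterns[right_patterns["phase"] == "anticipation"]
        .rename(columns={"beta": "response"})
        .merge(cdf[["subject", "diagnosis", "age", "gender"]], on="subject")
    )


def make_grouped_data(n_subjects=60, n_cond=4, sigma_subject=1.0, sigma_resid=1.0,
                      effects=None, seed=0):
    """Long-format data from the random-intercept model for LMM tests."""
    rng = np.random.default_rng(seed)
    effects = effects or {}
    rows = []
    groups = rng.choice(list("AB"), n_subjects)
    for i in range(n_subjects):
        b = rng.normal(0, sigma_subject)
        age = rng.uniform(20, 55)
        gender = rng.choice(["male", "female"])
        for c in range(n_cond):
            mu = effects.get((groups[i], c), 0.0)
            rows.append((f"S{i:03d}", groups[i], f"cond{c}", age, gender,
                         mu + b + rng.normal(0, sigma_resid)))
    return pd.DataFrame(rows, columns=["subject", "grp", "condition", "age",
                                       "gender", "response"])
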