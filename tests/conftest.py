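import numpy as np
import pandas as pd
import pytest

from sugarsim import (RunConfig, SyntheticConfig, generate_diaries,
                      generate_disease_tables, generate_population,
                      load_default_policy, run_pipeline)
from sugarsim.lifetable import DiseaseTable
from sugarsim.synthetic import generate_background_tables, generate_population_table


@pytest.fixture(scope="session")
def synth_config():
    return SyntheticConfig(n_people=300, seed=7)


@pytest.fixture(scope="session")
def people(synth_config):
    return generate_population(synth_config)


@pytest.fixture(scope="session")
def items(people, synth_config):
    return generate_diaries(people, synth_config)


@pytest.fixture(scope="session")
def policy():
    return load_default_policy()


@pytest.fixture(scope="session")
def disease_table():
    return DiseaseTable(generate_disease_tables(seed=3))


@pytest.fixture(scope="session")
def background():
    return generate_background_tables()


@pytest.fixture(scope="session")
def population():
    popn = generate_population_table()
    return popn[popn["age"] <= 80]


@pytest.fixture(scope="session")
def small_bundle():
    """One deterministic pipeline run on a small synthetic population,
    shared across tests that only inspect its structure."""
    return run_pipeline(RunConfig(seed=5, n_people=300, run_monte_carlo=False))


def single_disease_table(incidence, case_fatality, rr=1.1, rr_diabetes=1.0,
                         utility=0.1, cost=1000.0, name="disease_a",
                         ages=range(18, 111)):
    """Constant-rate one-disease table used by analytic-oracle tests."""
    frames = []
    for sex in ("male", "female"):
        frames.append(pd.DataFrame({
            "disease": name, "sex": sex, "age": list(ages),
            "incidence": incidence, "case_fatality": case_fatality,
            "rr_per_bmi_unit": rr, "rr_diabetes": rr_diabetes,
            "utility_decrement": utility, "annual_cost": cost,
        }))
    return DiseaseTable(pd.concat(frames, ignore_index=True))


def flat_background(mortality=0.01, utility=0.9, unrelated=1000.0,
                    ages=range(18, 111)):
    frames = []
    for sex in ("male", "female"):
        frames.append(pd.DataFrame({
            "sex": sex, "age": list(ages),
            "background_mortality": mortality,
            "baseline_utility": utility,
            "unrelated_cost": unrelated,
        }))
    return pd.concat(frames, ignore_index=True)


def two_cohort_population(age=40, count=10000.0):
    return pd.DataFrame({"sex": ["male", "female"], "age": [age, age],
                         "count": [count, count]})


def uniform_bmi_shift(delta=0.5, bmi=28.0, n=50, ages=(30, 70)):
    """A BMIShift with n people per sex spread over an age range, all
    shifted down by ``delta`` BMI units."""
    from sugarsim.lifetable import BMIShift

    rng = np.random.default_rng(11)
    shift = BMIShift()
    for sex in ("male", "female"):
        a = rng.integers(ages[0], ages[1] + 1, n)
        b0 = rng.normal(bmi, 3.0, n)
        shift.data[sex] = (a, b0, b0 - delta, np.ones(n))
    return shift
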