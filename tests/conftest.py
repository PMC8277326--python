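import warnings

import numpy as np
import pandas as pd
import pytest

import phenoscreen as ps
from phenoscreen.cohort import Cohort, VariableSchema

#: the 14 cluster-candidate variables of the default schema
CLUSTER14 = [
    "gender", "age", "bmi", "nonrepairing_sleep", "nocturia", "stroke",
    "arterial_hypertension", "pulmonary_hypertension",
    "congestive_heart_failure", "arrhythmias", "pacemaker",
    "respiratory_changes", "diabetes", "dyslipidemia",
]


@pytest.fixture(scope="session")
def default_spec():
    return ps.default_generator_spec(seed=0)


@pytest.fixture(scope="session")
def complete_cohort(default_spec):
    """One complete (no missingness) default cohort: 207 OSA / 111 healthy."""
    return ps.generate_cohort(default_spec)


@pytest.fixture(scope="session")
def masked_cohort(default_spec, complete_cohort):
    return ps.inject_missingness(complete_cohort, default_spec)


@pytest.fixture(scope="session")
def imputed_cohort(default_spec, masked_cohort):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kept, _ = ps.drop_high_missing(masked_cohort)
        screening = ps.univariate_screen(kept)
        return ps.impute_stepwise_knn(kept, screening)


@pytest.fixture(scope="session")
def osa_cluster_model(complete_cohort):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ps.fit_phenotypes(complete_cohort, CLUSTER14)


def make_binary_cohort(rows, categories=("no", "yes")):
    """Tiny hand-built cohort: rows = list of (value-dict, ahi)."""
    variables = sorted({k for values, _ in rows for k in values})
    schema = {
        v: VariableSchema(name=v, categories=tuple(categories)) for v in variables
    }
    data = []
    for i, (values, ahi) in enumerate(rows):
        sev = ps.severity_of_ahi(ahi)
        data.append(
            {"id": f"t{i}", **values, "ahi": ahi, "severity": sev, "osa": int(ahi >= 5)}
        )
    return Cohort(pd.DataFrame(data), schema)


@pytest.fixture
def rng():
    return np.random.default_rng(20210622)
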