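import numpy as np
import pandas as pd
import pytest

from csfmet import design_from_table1, generate
from csfmet.datatypes import Dataset, MetaboliteMatrix
from csfmet.preprocess import autoscale, impute_missing, occurrence_filter, sum_normalize


def prep(ds):
    """Standard preprocessing chain: normalise, filter, impute, autoscale."""
    m = impute_missing(occurrence_filter(sum_normalize(ds.matrix), ds.samples))
    X, state = autoscale(m)
    return m, X, state


@pytest.fixture(scope="session")
def cohort():
    """One default synthetic cohort (study design sizes)."""
    return generate(design_from_table1(seed=1))


@pytest.fixture(scope="session")
def prepped(cohort):
    """(dataset, normalised matrix, scaled matrix) for the default cohort."""
    m, X, _ = prep(cohort)
    return cohort, m, X


@pytest.fixture(scope="session")
def cohort_bank():
    """Twenty prepped cohorts for seed-averaged recovery experiments."""
    bank = []
    for seed in range(20):
        ds = generate(design_from_table1(seed=seed))
        m, X, _ = prep(ds)
        bank.append((ds, m, X))
    return bank


@pytest.fixture()
def toy_dataset():
    """Hand-written 3-sample x 2-metabolite dataset with one missing cell."""
    matrix = MetaboliteMatrix(pd.DataFrame(
        {"glucose": [10.0, 20.0, 30.0], "lactic acid": [1.0, np.nan, 3.0]},
        index=["s1", "s2", "s3"],
    ))
    samples = pd.DataFrame(
        {
            "group": ["CTRL", "MS", "MS"],
            "status": ["NONE", "REMISSION", "RELAPSE"],
            "edss": [0.0, 2.5, 6.0],
            "ocb": [0.0, 1.0, np.nan],
            "protein": [30.0, 55.0, 80.0],
            "wbc": [1.0, 5.0, 12.0],
            "igg_index": [0.5, 0.9, 0.7],
        },
        index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
    )
    metabolites = pd.DataFrame(
        {
            "name": ["glucose", "lactic acid"],
            "chem_class": ["sugar", "organic_acid"],
            "fingerprint": [np.array([1, 0, 1, 0], dtype=np.uint8),
                            np.array([1, 1, 0, 0], dtype=np.uint8)],
            "compound_id": ["CID1", "CID2"],
            "pathways": [frozenset({"Glycolysis"}), frozenset({"Glycolysis"})],
            "rpair_partners": [frozenset({"lactic acid"}), frozenset({"glucose"})],
        },
        index=pd.Index(["glucose", "lactic acid"], name="metabolite_id"),
    )
    return Dataset(matrix, samples, metabolites)
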