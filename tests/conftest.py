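import numpy as np
import pandas as pd
import pytest

from icb_bench.simulate import CohortBundle, default_config, generate_cohorts


@pytest.fixture(scope="session")
def default_bundles():
    """The five default synthetic cohorts (three RNA+WES, two WES-only)."""
    return generate_cohorts(default_config(seed=7))


@pytest.fixture()
def toy_expression():
    """A printed 6-gene x 3-patient TPM matrix used for hand-checked scores."""
    return pd.DataFrame(
        {
            "P1": [0.0, 7.0, 15.0, 3.0, 1.0, 31.0],
            "P2": [1.0, 0.0, 3.0, 7.0, 63.0, 0.0],
            "P3": [15.0, 15.0, 0.0, 0.0, 7.0, 7.0],
        },
        index=pd.Index(
            ["CXCL10", "CXCL9", "HLA-DRA", "IDO1", "IFNG", "STAT1"], name="gene"
        ),
    )


@pytest.fixture()
def tiny_clinical():
    return pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(1, 7)],
            "response_category": ["CR", "PD", "PD", "NB", "SD", "PD"],
            "os_value": [0.5, 3.0, 1.0, np.nan, 2.5, np.nan],
            "os_unit": ["years"] * 6,
            "os_known": [True, True, True, False, True, False],
        }
    )


def make_rna_bundle(expression: pd.DataFrame, responses=None) -> CohortBundle:
    """Wrap an expression matrix in a minimal RNA-only cohort."""
    patients = list(expression.columns)
    if responses is None:
        responses = ["CR" if i % 2 == 0 else "NB" for i in range(len(patients))]
    clinical = pd.DataFrame(
        {
            "patient_id": patients,
            "response_category": responses,
            "os_value": np.nan,
            "os_unit": "years",
            "os_known": False,
        }
    )
    return CohortBundle(
        cohort_id="toy",
        clinical=clinical,
        expression=expression,
        rna_available=True,
        dna_available=False,
    )
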