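import numpy as np
import pytest

from uroevmir.simulate import CohortDesign, generate_reference, simulate_cohort_counts

ADAPTER = "AGATCGGAAGAGCACACGTC"


@pytest.fixture(scope="session")
def small_reference():
    # min_length=20 so every simulated read survives the >19 bp insert filter
    return generate_reference(50, seed=7, min_length=20)


@pytest.fixture(scope="session")
def small_design():
    """A fast ~90-sample cohort with the default planted panel."""
    return CohortDesign(
        n_pdac_by_stage={"0": 1, "IA": 5, "IB": 5, "IIA": 4, "IIB": 8,
                         "III": 10, "IV": 12},
        n_hr_by_risk={"ductal_dilation": 3, "T2DM": 12,
                      "chronic_pancreatitis": 5, "pancreatic_cysts": 4,
                      "IPMN": 10, "family_history": 6},
        n_general=8,
        n_mirnas=120,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_design):
    return simulate_cohort_counts(small_design)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
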