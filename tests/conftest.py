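import numpy as np
import pytest

import npxpanel as npx


@pytest.fixture(scope="session")
def params_bvc():
    """Packaged group statistics, benign vs cancer parameterization."""
    return npx.load_fixture_params("benign_vs_cancer")


@pytest.fixture(scope="session")
def params_bvbc():
    """Packaged group statistics, benign vs borderline+cancer."""
    return npx.load_fixture_params("benign_vs_borderline_cancer")


@pytest.fixture(scope="session")
def paper_cohort(params_bvc):
    """One simulated cohort with the enrolled composition (180 samples,
    8 flagged QC failures, panel padded to 177 proteins)."""
    return npx.simulate_cohort(params_bvc, npx.CohortConfig(seed=12345))


@pytest.fixture(scope="session")
def clean_cohort(paper_cohort):
    return npx.apply_qc(paper_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(987)
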