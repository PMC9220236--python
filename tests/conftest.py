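"""Shared fixtures.

The replicate-fit fixtures are session-scoped because each one runs a full
simulation-estimation study (20 replicate datasets fitted by FOCE-I); they
are shared between the sparse-sampling bias checks and the downstream
AUC/MIC target-attainment checks, mirroring how the study reuses one set of
fits for both analyses.
"""

import pytest

from sparse_pkpd.workflow import replicate_fits

#: Master seed fixing the synthetic study conditions for the test session.
MASTER_SEED = 1234

#: Replicate datasets per scenario (desk-scale study size).
N_REPLICATES = 20


@pytest.fixture(scope="session")
def fits_2cmt_truth_1cmt_n50():
    """One-compartment fits (4-point design) of two-compartment-truth data."""
    return replicate_fits(2, 1, 50, N_REPLICATES, MASTER_SEED)


@pytest.fixture(scope="session")
def fits_2cmt_truth_2cmt_n50():
    """Matched two-compartment fits (6-point design) of two-compartment data."""
    return replicate_fits(2, 2, 50, N_REPLICATES, MASTER_SEED)


@pytest.fixture(scope="session")
def fits_3cmt_truth_1cmt_n12():
    """One-compartment fits (4-point design) of three-compartment-truth data."""
    return replicate_fits(3, 1, 12, N_REPLICATES, MASTER_SEED)


@pytest.fixture(scope="session")
def fits_3cmt_truth_3cmt_n50():
    """Matched three-compartment fits (9-point design) of three-compartment data."""
    return replicate_fits(3, 3, 50, N_REPLICATES, MASTER_SEED)
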