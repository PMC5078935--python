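import numpy as np
import pytest

from csfpk import PKParameters, Regimen, table4_median_parameters


@pytest.fixture(scope="session")
def median_params() -> PKParameters:
    """Population-median parameter vector from the packaged summary table."""
    return table4_median_parameters()


@pytest.fixture(scope="session")
def q8_regimen() -> Regimen:
    """2000 mg every 8 h as 4-h infusions, 12 doses (4 days)."""
    return Regimen.repeating(2000.0, 8.0, 4.0, 12)


@pytest.fixture(scope="session")
def two_point_truth():
    """A well-separated two-point population for recovery experiments."""
    p1 = PKParameters(cl=10.0, v_c=12.0, k_cp=1.0, k_pc=1.5, k_cb=0.02, k_bc=0.05, v_csf=80.0)
    p2 = PKParameters(cl=20.0, v_c=6.0, k_cp=2.0, k_pc=0.8, k_cb=0.1, k_bc=0.15, v_csf=50.0)
    return [p1, p2], np.array([0.5, 0.5])
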