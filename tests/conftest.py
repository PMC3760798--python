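import numpy as np
import pytest

from relacbp import (default_parameters, default_tnf_curve, equilibrate,
                     simulate, scan_kmrna)


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def unmodified_params():
    return default_parameters(modified=False)


@pytest.fixture(scope="session")
def tnf_curve():
    return default_tnf_curve()


@pytest.fixture(scope="session")
def resting_state(params, tnf_curve):
    return equilibrate(params, tnf_curve)


@pytest.fixture(scope="session")
def wt_trajectory(params, tnf_curve, resting_state):
    return simulate(params, tnf_curve, t_end=240.0, dt_out=1.0,
                    x0=resting_state.copy())


@pytest.fixture(scope="session")
def kmrna_scan_120(params, tnf_curve):
    """k_mRNA suppression scan over the 120-min experimental window."""
    return scan_kmrna(params, tnf_curve, t_end=120.0, dt_out=1.0)
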