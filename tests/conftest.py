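import numpy as np
import pytest

from mdoe.model import ReferenceYeastModel
from mdoe.synthetic import s1_scenario, s2_scenario


@pytest.fixture(scope="session")
def ref_model():
    return ReferenceYeastModel()


@pytest.fixture(scope="session")
def s1_trajectory():
    """One nominal growth-study simulation, reused by several suites."""
    sc = s1_scenario()
    return sc, sc.simulate()


@pytest.fixture(scope="session")
def s2_trajectory():
    sc = s2_scenario()
    return sc, sc.simulate()


@pytest.fixture(scope="session")
def zero_rate_params(ref_model):
    """Reference parameters with every kinetic/transfer rate set to zero."""
    p = ref_model.default_parameters()
    zeroed = (
        "qGlc_ox_max",
        "qGlc_ferm_max",
        "qEtOH_max",
        "qEAA_max",
        "k_act",
        "k_pp",
        "k_inact",
        "k_d",
    )
    values = dict(p.values)
    bounds = dict(p.bounds)
    for k in zeroed:
        values[k] = 0.0
        bounds[k] = (0.0, bounds[k][1])
    from mdoe.model import ModelParameters

    return ModelParameters(values=values, bounds=bounds, units=dict(p.units))
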