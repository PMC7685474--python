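import warnings

import pytest

from af4saxs.fff_retention import FlowConditions, SolventConditions
from af4saxs.synthetic_data import default_calibrated_geometry


@pytest.fixture(scope="session")
def solvent():
    return SolventConditions()


@pytest.fixture(scope="session")
def flows():
    return FlowConditions(elution_duration_min=12.0)


@pytest.fixture(scope="session")
def calibrated_geometry(flows, solvent):
    """Channel calibrated so the HSA monomer (3.3 nm) elutes at 4.5 min."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return default_calibrated_geometry(flows, solvent)
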