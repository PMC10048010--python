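import numpy as np
import pytest

import crownmorph as cm
from oracles import make_paraboloid_fixture


@pytest.fixture(scope="session")
def fp_reference():
    return cm.make_reference_crown(cm.Tooth.FP)


@pytest.fixture(scope="session")
def sp_reference():
    return cm.make_reference_crown(cm.Tooth.SP)


@pytest.fixture(scope="session")
def molar_reference():
    return cm.make_reference_crown(cm.Tooth.M)


@pytest.fixture(scope="session")
def paraboloid():
    return make_paraboloid_fixture()


@pytest.fixture(scope="session")
def small_cohort():
    """12 + 12 specimens, both premolars, with meshes (seed fixed)."""
    spec = cm.DimorphismSpec(
        teeth=(cm.Tooth.FP, cm.Tooth.SP), n_f=12, n_m=12, seed=11
    )
    return cm.generate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
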