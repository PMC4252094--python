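import numpy as np
import pytest

from pseudoaldo import (DoseRegimen, default_electrolyte_params, default_hsd2_params,
                        default_raas_params, load_parameters)


@pytest.fixture(scope="session")
def rat_config():
    return load_parameters(species="rat")


@pytest.fixture(scope="session")
def human_config():
    return load_parameters(species="human")


@pytest.fixture(scope="session")
def hsd2_params():
    return default_hsd2_params()


@pytest.fixture(scope="session")
def raas_params():
    return default_raas_params()


@pytest.fixture(scope="session")
def electrolyte_params():
    return default_electrolyte_params()


@pytest.fixture(scope="session")
def ga500_regimen():
    """Oral GA 250 mg twice daily for one week (full-cascade validation run)."""
    return DoseRegimen(compound="GA", route="po", dose_amount=250.0,
                       dose_times=(0.0, 10.0), n_days=7)
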