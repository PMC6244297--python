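import numpy as np
import pandas as pd
import pytest

from glacialch4.config import default_config


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture
def rng():
    return np.random.default_rng(20140508)


@pytest.fixture(scope="session")
def upwelling_samples():
    """Six subglacial-upwelling samples mirroring the 2014 late-season
    field campaign row: mean 17.57 mg/l, range 11.71-21.73, n = 6."""
    # constructed so that mean/min/max match the published summary exactly
    conc = [11.71, 21.73, 18.50, 19.00, 17.00, 17.48]
    assert abs(np.mean(conc) - 17.57) < 1e-12
    return pd.DataFrame(
        {
            "sample_id": [f"su{i}" for i in range(6)],
            "site_class": "subglacial_upwelling",
            "campaign_year": 2014,
            "day_of_year": 200,
            "phase": "late_post",
            "ch4_aq_mg_l": conc,
            "d13C_permil": [-60.22, -58.56, -59.6, -59.8, -59.4, -60.02],
            "dD_permil": [-324.3, -322.6, -323.9, -324.0, np.nan, np.nan],
        }
    )
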