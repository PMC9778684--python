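import numpy as np
import pytest

import soilptf as sp


@pytest.fixture(scope="session")
def scp_kf_model():
    return sp.get_builtin_model("table4", "SCP", "Kf")


@pytest.fixture(scope="session")
def soils_50(scp_kf_model):
    """Seeded soils on which the main sulfonamide truth models stay positive.

    Several tests build noise-free or low-noise records straight from a
    truth model; restricting to soils with a comfortably positive truth
    value keeps sorption parameters valid without engaging any floor.
    """
    pool = sp.generate_soils(sp.GeneratorConfig(n_soils=200, seed=20260920))
    kept = [s for s in pool if sp.predict(scp_kf_model, s).value > 1.0]
    assert len(kept) >= 50
    return kept[:50]
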