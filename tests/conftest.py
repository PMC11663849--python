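import numpy as np
import pytest
from hypothesis import settings

from epfsit.bioassay import MortalityRecord

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


def make_mortality(days, deaths, n_initial, treatment="T", replicate="R1"):
    """Cumulative mortality records from parallel day/death lists."""
    return [
        MortalityRecord(
            treatment_id=treatment,
            replicate=replicate,
            day=int(d),
            n_initial=int(n_initial),
            n_dead_cum=int(k),
        )
        for d, k in zip(days, deaths)
    ]
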