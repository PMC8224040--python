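import numpy as np
import pytest
from hypothesis import settings

from anchorkit import simdata

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def orthogroup_panel():
    """20 orthogroups, 8 taxa, one planted 60-AA conserved block each,
    absent-taxon counts cycling 0..4 to straddle the 5-of-8 rule."""
    return simdata.simulate_orthogroups(
        20, 8, seed=101, absent_counts=[0, 1, 2, 3, 4]
    )


@pytest.fixture(scope="session")
def small_targets():
    rng = np.random.default_rng(202)
    return {
        f"t{i + 1:02d}": "".join(rng.choice(list("ACGT"), size=int(rng.integers(180, 400))))
        for i in range(8)
    }
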