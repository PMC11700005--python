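import numpy as np
import pytest

from tddscope import battery as bt


@pytest.fixture(scope="session")
def acceptance_battery():
    """Desk-scale simulation battery shared by the acceptance tests.

    Standard 10-radius grid at v_in = 0.52 with k in {0, 20} s^-1, plus the
    exchange sweep at r = 2 um and the cancer-cell-range extras, simulated at
    the reduced preset (2e4 walkers, dt = 2e-3 ms) for both protocol contrast
    pairs.  Takes several minutes; session-scoped so it runs once.
    """
    table = bt.run_battery(
        radii_um=bt.STANDARD_RADII,
        ks_per_s=(0.0, 20.0),
        extra_substrates=[(2.0, 1.0), (2.0, 2.0), (2.0, 8.0), (5.0, 0.0), (5.0, 20.0)],
        seed=20240917,
    )
    return bt.summarize_battery(table), table


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
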