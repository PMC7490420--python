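import numpy as np
import pandas as pd
import pytest

from predimr.instruments import HarmonizedInstrumentSet


def make_harmonized(gamma, se_x, Gamma, se_y, exposure_id="exp", outcome_id="out"):
    """Build a HarmonizedInstrumentSet directly from effect arrays."""
    gamma = np.asarray(gamma, float)
    n = gamma.size
    df = pd.DataFrame(
        dict(
            rsid=[f"rs{i + 1:04d}" for i in range(n)],
            effect_allele=["A"] * n,
            other_allele=["G"] * n,
            gamma=gamma,
            se_x=np.asarray(se_x, float),
            Gamma=np.asarray(Gamma, float),
            se_y=np.asarray(se_y, float),
            eaf_x=np.full(n, 0.3),
            eaf_y=np.full(n, 0.3),
        )
    )
    return HarmonizedInstrumentSet(exposure_id, outcome_id, df)


@pytest.fixture
def harmonized_factory():
    return make_harmonized


def random_instrument_set(rng, n=10):
    """A well-conditioned random instrument set for oracle comparisons."""
    gamma = rng.uniform(0.05, 0.2, n)
    se_x = rng.uniform(0.002, 0.01, n)
    se_y = rng.uniform(0.005, 0.05, n)
    Gamma = rng.normal(0.3 * gamma, se_y)
    return make_harmonized(gamma, se_x, Gamma, se_y)
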