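import numpy as np
import pytest

from twinace import OptimizerOptions, TraitSpec, simulate
from twinace.simulate import GeneratingParams, default_wellbeing_params

#: cheap optimizer settings for tests (single moment-based start converges
#: reliably on well-conditioned simulated data)
FAST = OptimizerOptions(n_starts=1, seed=0)


@pytest.fixture(scope="session")
def wellbeing_params():
    """Trivariate study-scale generating parameters (429 MZ / 707 DZ)."""
    return default_wellbeing_params(seed=20110101)


@pytest.fixture(scope="session")
def wellbeing_table(wellbeing_params):
    return simulate(wellbeing_params)


@pytest.fixture(scope="session")
def big_params():
    """The same trivariate structure at 100k pairs per zygosity group, for
    Monte-Carlo comparisons against closed-form population quantities."""
    return default_wellbeing_params(nMZ=100_000, nDZ=100_000, seed=7)


@pytest.fixture(scope="session")
def big_table(big_params):
    return simulate(big_params)


@pytest.fixture
def univariate_params():
    def make(a=0.4, c=0.2, nMZ=500, nDZ=500, seed=0, **kw):
        e = 1.0 - a - c
        return GeneratingParams(
            traits=TraitSpec(["y"]), a=[a], c=[c], e=[e], nMZ=nMZ, nDZ=nDZ, seed=seed, **kw
        )

    return make
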