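import numpy as np
import pytest

from survselect import DistributionSpec

# arms used repeatedly across the suite (benchmark design anchors)
WEIBULL_ARM1 = DistributionSpec("weibull", rate=0.10, shape=2.0)
WEIBULL_ARM2 = DistributionSpec("weibull", rate=0.09, shape=2.4)
GENEXP_ARM1 = DistributionSpec("genexp", rate=0.10, shape=2.0)
GENEXP_ARM2 = DistributionSpec("genexp", rate=0.09, shape=2.4)
EXP_SLOW = DistributionSpec("exponential", rate=0.12)
EXP_FAST = DistributionSpec("exponential", rate=0.08)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240228)
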