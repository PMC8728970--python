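import pytest

from cytopower import GroupSpec, TestSpec


@pytest.fixture
def trial_arms():
    """Arms of the worked clinical-trial design: immune-cell fraction
    18.6% vs 28.6%, SD 5% in both arms, 1000 cells per specimen."""
    g0 = GroupSpec(m=6, n=1000, mu=0.186, sigma=0.05)
    g1 = GroupSpec(m=6, n=1000, mu=0.286, sigma=0.05)
    return g0, g1


@pytest.fixture
def rare_arms():
    """A rare cell type (3% vs 5%), where finite-cell noise matters most."""
    g0 = GroupSpec(m=8, n=1000, mu=0.03, sigma=0.015)
    g1 = GroupSpec(m=8, n=1000, mu=0.05, sigma=0.01)
    return g0, g1


@pytest.fixture
def one_sided():
    return TestSpec(alpha=0.05, sides="one_sided", design="unpaired")
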