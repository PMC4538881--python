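import pytest

from filterbench.simulate import SimConfig, evolve


@pytest.fixture(scope="session")
def main_family():
    """One family under the main study configuration (30 taxa, 250 PAM)."""
    return evolve(SimConfig(seed=20240917))


@pytest.fixture(scope="session")
def small_family():
    """A small, fast family for pipeline-level tests."""
    return evolve(SimConfig(n_taxa=8, seed=11))


@pytest.fixture(scope="session")
def clean_family():
    """Strong-signal regime: no indels, long sequences, mild divergence,
    and a tree whose internal branches are all a few PAM long."""
    return evolve(SimConfig(n_taxa=6, depth_pam=80.0, indel_rate=0.0,
                            gamma_k=2500.0, gamma_theta=1.0, seed=7))
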