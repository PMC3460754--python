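import pytest

from hgtscan.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_sim():
    """A small noisy simulation with enough planted HGT to exercise every
    downstream stage."""
    cfg = SimulationConfig(
        seed=11,
        n_clusters=40,
        hgt_fraction=0.25,
        noise_fraction=0.1,
        host_like_vgt_fraction=0.2,
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def clean_sim():
    """Noise-free simulation: classifier output must equal planted truth."""
    cfg = SimulationConfig(
        seed=5, n_clusters=60, hgt_fraction=0.3, noise_fraction=0.0
    )
    return simulate_study(cfg)
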