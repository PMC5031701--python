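import numpy as np
import pytest

from donormix import PanelLocus, SimulationConfig, simulate_sample


@pytest.fixture
def small_panel():
    """Four loci: three autosomal (chr naming mixed), one Y."""
    return [
        PanelLocus("rs1", "1", 1000, "A", "G", True),
        PanelLocus("rs2", "2", 2000, "C", "T", True),
        PanelLocus("rs3", "17", 500, "A", "C", True),
        PanelLocus("rsY", "Y", 777, "C", "T", False),
    ]


@pytest.fixture
def sample_2pct():
    """One seeded synthetic sample at 2% donor, validation-scale settings."""
    cfg = SimulationConfig(donor_fraction=0.02, seed=20)
    panel, truth, counts = simulate_sample(cfg)
    return cfg, panel, truth, counts


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
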