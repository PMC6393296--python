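import numpy as np
import pytest

from dnacurtain import SimulationConfig, simulate_ensemble


@pytest.fixture(scope="session")
def brownian_ensemble():
    """100 noise-free Brownian trajectories, D=0.1 um^2/s, no obstacles."""
    cfg = SimulationConfig(
        diffusion_coefficient=0.1,
        localization_sigma=0.0,
        n_frames=400,
        dna_length=200.0,  # effectively unbounded over this horizon
        start_position=100.0,
        seed=42,
    )
    trajectories, truths = simulate_ensemble(cfg, 100)
    return cfg, trajectories, truths
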