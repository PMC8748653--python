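import numpy as np
import pytest

from phasorplex.codebook import Codebook, FluorophoreSpec, build_codebook
from phasorplex.simulate import SimulationConfig, default_panel

REP = 78e6  # Hz, pulsed-laser repetition frequency used throughout


@pytest.fixture(scope="session")
def panel5():
    return default_panel(5)


@pytest.fixture(scope="session")
def codebook10(panel5):
    """Ten pair codewords from five spectrally distinct dyes."""
    return build_codebook(panel5, [f"gene{i}" for i in range(10)])


@pytest.fixture(scope="session")
def lifetime_pair_codebook():
    """Two same-channel dyes (1 ns and 3.5 ns) plus singleton/pair codewords,
    the minimal lifetime-combinatorial configuration."""
    dyes = [
        FluorophoreSpec("short", 660.0, 8.0, 1.0, 0),
        FluorophoreSpec("long", 662.0, 8.0, 3.5, 0),
    ]
    return Codebook(
        fluorophores=dyes,
        codewords={"t_short": ("short",), "t_both": ("short", "long"), "t_long": ("long",)},
        n_channels=1,
    )


@pytest.fixture()
def small_sim_config(codebook10):
    """Low-density 10-plex stack small enough for per-test use."""
    return SimulationConfig(
        codebook=codebook10,
        volume_um=(15.0, 15.0, 4.5),
        counts_per_target=5,
        n_time_bins=64,
        seed=11,
    )
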