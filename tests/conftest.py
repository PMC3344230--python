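import numpy as np
import pytest

from reticulator.alignment import Alignment
from reticulator.simulate import SimulationConfig, simulate_histogram


@pytest.fixture
def small_gap_alignment() -> Alignment:
    return Alignment(("A", "B", "C"), ("AC--GT", "ACTTGT", "A---GT"))


@pytest.fixture
def reference_alignment() -> Alignment:
    """Tiny allele-exemplar alignment with a 4-column diagnostic deletion
    carried by group Y (columns 4-8)."""
    return Alignment(
        ("X1", "X2", "Y"),
        (
            "ACGTACGTACGTACGT",
            "ACGTACGTACGAACGT",
            "TCGT----ACGTACGA",
        ),
    )


@pytest.fixture
def two_peak_histogram():
    rng = np.random.default_rng(123)
    return simulate_histogram(2, SimulationConfig(seed=123), rng, sample_id="s1")
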