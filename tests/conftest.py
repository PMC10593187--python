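import numpy as np
import pytest

from recyclect.sequence import PhaseSequence


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def raw_sequence(rng):
    """8-phase looped raw12bit sequence of random 16x16 integer frames."""
    frames = [rng.integers(0, 4096, size=(16, 16)).astype(np.float64) for _ in range(8)]
    return PhaseSequence(
        frames=frames, intensity_scale="raw12bit", looped=True, domain_label="low_dose"
    )


def scalar_sequence(values, looped=False):
    """Sequence of 1x1 'frames' used for hand-checkable loss fixtures."""
    return PhaseSequence(
        frames=[np.full((1, 1), float(v)) for v in values],
        intensity_scale="model",
        looped=looped,
        domain_label="low_dose",
    )
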