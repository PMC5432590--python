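import numpy as np
import pytest


def spawn_seeds(base: int, n: int):
    """Deterministic list of 31-bit child seeds from one base seed."""
    return [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(base).spawn(n)
    ]


@pytest.fixture
def seeds():
    return spawn_seeds
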