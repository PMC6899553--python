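import numpy as np
import pytest

from mpasl import RAT_PULSE_TRAIN, build_lookup


@pytest.fixture(scope="session")
def rat_lookup():
    """Full-resolution preclinical lookup table (200 phases x 7 speeds).

    Built once per session; deterministic physics, so shared freely.
    """
    return build_lookup(RAT_PULSE_TRAIN)


@pytest.fixture(scope="session")
def small_lookup():
    """Coarse rat table for fast structural tests."""
    return build_lookup(RAT_PULSE_TRAIN, velocities=(10.0, 20.0, 40.0), n_phase=33)
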