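import numpy as np
import pytest

from heartsync.phase_engine import DriftOffset, Frame, ReferenceSequence
from heartsync.synthetic_heart import SyntheticHeartSpec


@pytest.fixture
def clean_spec():
    """Deterministic, noise-free beating heart with an exact 20-frame period."""
    return SyntheticHeartSpec(
        mean_period=0.25,
        period_jitter_cv=0.0,
        refractory_jitter_cv=0.0,
        morph_rate=0.0,
        drift_velocity=(0.0, 0.0),
        noise_sd=0.0,
        blood_speckle_rate=0.0,
        seed=0,
    )


def make_reference(stack, period_frames=None, sequence_id=0, barrier=0):
    """ReferenceSequence over a pixel stack, pads wrapped cyclically."""
    stack = np.asarray(stack, dtype=np.float32)
    frames = [Frame(stack[i], i * 0.0125, i) for i in range(len(stack))]
    return ReferenceSequence(
        frames=frames,
        pad_before=[frames[-2], frames[-1]],
        pad_after=[frames[0], frames[1]],
        period_frames=period_frames or float(len(stack)),
        barrier_frame=barrier,
        acquired_at=0.0,
        sequence_id=sequence_id,
    )


@pytest.fixture
def reference_factory():
    return make_reference


@pytest.fixture
def zero_drift():
    return DriftOffset()
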