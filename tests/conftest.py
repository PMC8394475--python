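import numpy as np
import pytest
from hypothesis import settings

from arval.synthetic import (
    GeneratorConfig,
    SubjectProfile,
    degrade_to_reference,
    degrade_to_tg,
    generate_ground_truth,
)

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def identity_generator(**overrides) -> GeneratorConfig:
    """Generator config with every degradation switched off."""
    base = dict(
        ref_noise_sd=0.0,
        tg_noise_sd=0.0,
        tg_wander_sd=0.0,
        tg_rot_noise_sd=0.0,
        injected_lag=0.0,
        frame_rotation=(0.0, 0.0, 0.0),
        frame_offset=(0.0, 0.0, 0.0),
        drift_rate=0.0,
        seed=0,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


@pytest.fixture
def reference_subject() -> SubjectProfile:
    """A subject at exactly the reference stature (1750 mm)."""
    return SubjectProfile(subject_id="REF", height=1750.0, seed=0)


@pytest.fixture
def clean_trial(reference_subject):
    """Noise-free, perfectly registered trial-1 recordings."""
    cfg = identity_generator(rep_jitter_frac=0.0)
    truth = generate_ground_truth(reference_subject, cfg)
    return truth, degrade_to_reference(truth, cfg), degrade_to_tg(truth, cfg)
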