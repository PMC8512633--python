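import logging

import pytest

from ecgpeaks import PipelineConfig, SynthConfig, generate, train_model
from ecgpeaks.benchmarks import mixed_noise_records

logging.getLogger("ecgpeaks").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def pipeline_config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def clean_record():
    """Noise-free synthetic ECG: Gaussian morphology only."""
    return generate(
        SynthConfig(duration=30.0, seed=3, white_noise_sd=0.0, baseline_wander=(0.0, 0.33), powerline=(0.0, 60.0))
    )


@pytest.fixture(scope="session")
def default_record():
    """Synthetic ECG at the default (mild) noise levels."""
    return generate(SynthConfig(duration=30.0, seed=5))


@pytest.fixture(scope="session")
def small_model(pipeline_config):
    """A detector trained on a handful of short mixed-noise records —
    enough structure for pipeline behaviour tests without the full-scale
    training run."""
    records = mixed_noise_records(6, duration=30.0, seed0=0)
    return train_model(records, pipeline_config)
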