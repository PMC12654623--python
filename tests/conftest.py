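import numpy as np
import pytest

from hybridbci import (
    PipelineConfig,
    Recording,
    SimulationConfig,
    build_pipeline_data,
    simulate_recordings,
)


@pytest.fixture
def protocol_recording() -> Recording:
    """A protocol-conformant untrimmed trial of deterministic samples."""
    rng = np.random.default_rng(42)
    return Recording(
        subject_id="sub01",
        session="morning",
        class_label="up_down",
        repetition=1,
        samples=rng.standard_normal((4096, 4)) * 10.0,
    )


@pytest.fixture(scope="session")
def tiny_config() -> PipelineConfig:
    """One subject, three repetitions: enough rows for every pipeline path."""
    sim = SimulationConfig(n_subjects=1, reps_per_class=3, seed=11)
    return PipelineConfig(sim=sim, n_repetitions=1, seed=11)


@pytest.fixture(scope="session")
def tiny_data(tiny_config):
    return build_pipeline_data(tiny_config, simulate_recordings(tiny_config.sim))
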