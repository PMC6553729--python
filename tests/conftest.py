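import pytest

from gaitsync import GaitParams, generate_pair_scene


@pytest.fixture
def default_params() -> GaitParams:
    """Noise-free 5 s scene at 30 fps, cadence 1.8 steps/s."""
    return GaitParams(step_frequency=1.8, seed=7)


@pytest.fixture
def clean_scene(default_params):
    return generate_pair_scene(default_params)


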