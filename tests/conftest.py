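import numpy as np
import pytest

import uavfvc as uv


@pytest.fixture(scope="session")
def default_scene():
    """Default 256x256 synthetic scene (vegetation fraction 0.36)."""
    return uv.generate_scene(uv.SceneConfig(rows=256, cols=256, seed=7))


@pytest.fixture(scope="session")
def pipeline_report(tmp_path_factory):
    """One full pipeline run on the default scene, shared across tests."""
    outdir = tmp_path_factory.mktemp("pipeline")
    return uv.run(uv.PipelineConfig(seed=7), outdir), outdir


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
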