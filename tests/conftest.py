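import numpy as np
import pytest

from grainseg.config import Config
from grainseg.model import scene_to_record
from grainseg.synthgrain import GrainSceneSpec, generate_scene
from grainseg.train import train


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def dense_scene():
    """One deterministic 128-px scene with six grains (the overfit target)."""
    spec = GrainSceneSpec(canvas=(128, 128), n_grains=6, n_classes=8)
    return generate_scene(spec, seed=7)


@pytest.fixture(scope="session")
def dense_record(dense_scene):
    return scene_to_record(dense_scene)


@pytest.fixture(scope="session")
def overfit_run(dense_record):
    """Tiny-mode model trained for the configured 300 iterations on the
    single dense scene.  Session-scoped: several tests probe different
    aspects of this one run."""
    cfg = Config.tiny(seed=1)
    model, history = train(cfg, [dense_record])
    return model, history
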