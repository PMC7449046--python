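import numpy as np
import pytest

from lprseg.synthetic import SceneConfig, generate_scene


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_scene():
    """One 96x96 scene with all three classes present."""
    cfg = SceneConfig(height=96, width=96, n_leaves=(4, 7),
                      n_panicles=(2, 4), seed=5)
    image, mask = generate_scene(cfg)
    counts = mask.class_counts()
    assert (counts > 0).all()
    return cfg, image, mask
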