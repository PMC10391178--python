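import numpy as np
import pytest

from teadet.synthetic import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_scene():
    """One small dense scene shared across read-only tests."""
    cfg = SceneConfig(width=160, height=128, n_objects=(20, 30),
                      mean_rel_scale=0.06)
    return generate_scene(cfg, seed=11)


@pytest.fixture(scope="session")
def tiny_corpus():
    """A handful of small frames for detector training/eval tests."""
    out = []
    for s in range(6):
        cfg = SceneConfig(width=128, height=128, n_objects=(8, 14),
                          mean_rel_scale=0.10)
        tri, ann = generate_scene(cfg, seed=40 + s)
        out.append((tri.rgb, ann))
    return out
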