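import numpy as np
import pytest

from leafknot import pipeline, synth


@pytest.fixture(scope="session")
def fig1d():
    """Worked-example preset: blade, 2 OL outlines, 2 OL sinuses, 2 TL sinuses."""
    return synth.make_leaf(synth.preset("fig1d", seed=1))


@pytest.fixture(scope="session")
def fig1d_result(fig1d):
    image, _ = fig1d
    return pipeline.run_pipeline(image)


@pytest.fixture(scope="session")
def preset_results():
    """(ground truth, pipeline result) for every preset at seed 1."""
    out = {}
    for name in sorted(synth.PRESETS):
        image, truth = synth.make_leaf(synth.preset(name, seed=1))
        out[name] = (truth, pipeline.run_pipeline(image))
    return out


@pytest.fixture(scope="session")
def noiseless_fig1d():
    """Noise-free render: pixel-exact class membership is knowable."""
    return synth.make_leaf(synth.preset("fig1d", seed=0, noise_sigma=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
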