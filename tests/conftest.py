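import numpy as np
import pytest
from shapely.geometry import Point

from dysquant import simulate
from dysquant.config import PipelineConfig
from dysquant.simulate import RenderConfig


@pytest.fixture(scope="session")
def noiseless_config():
    """Noise-free, blur-free, zero-background rendering for identity tests."""
    return RenderConfig(
        image_size=(256, 256),
        noise_sd=0.0,
        blur_sigma=0.0,
        background_level=0.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def disk_fiber():
    """A single circular fiber centered in a 256x256 frame."""
    return Point(128, 128).buffer(40, quad_segs=64)


@pytest.fixture(scope="session")
def dmd_section():
    """DMD-preset section at default (noisy, blurred) rendering."""
    return simulate.simulate_section("DMD", 150, seed=7, image_size=(768, 768))


@pytest.fixture(scope="session")
def ctrl_section():
    return simulate.simulate_section("CTRL", 150, seed=1, image_size=(768, 768))


@pytest.fixture(scope="session")
def clean_section():
    """Noise-free render of 100 fibers (blur still on) for segmentation tests."""
    config = RenderConfig(image_size=(1024, 1024), noise_sd=0.0, seed=5)
    ss = np.random.SeedSequence(5).spawn(3)
    geo, samp, phase = (int(s.generate_state(1)[0]) for s in ss)
    polys = simulate.generate_geometry(100, (1024, 1024), gap=3.0, seed=geo)
    samples = simulate.sample_fibers(simulate.PRESETS["DMD"], len(polys), seed=samp)
    fibers = simulate.build_fiber_specs(polys, samples, seed=phase)
    return simulate.render_section(fibers, config)


@pytest.fixture()
def default_config():
    return PipelineConfig()
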