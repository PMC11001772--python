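import numpy as np
import pytest

from sonomorph import chamber, synth


@pytest.fixture(scope="session")
def ring_field():
    return chamber.round_mode_field(
        chamber.ModeSpec("round", m=0, n=4, chamber_dim=21.0,
                         grid_resolution=256))


@pytest.fixture(scope="session")
def square_field():
    return chamber.square_mode_field(
        chamber.ModeSpec("square", m=5, n=1, chamber_dim=15.0,
                         grid_resolution=251))


@pytest.fixture(scope="session")
def ring_image():
    """Desk-scale patterned rings image with programmed 438% enhancement."""
    spec = synth.ImageSpec("rings", image_size=1024, pixel_pitch=5.0,
                           background_fraction=0.05, enhancement_pct=438.0,
                           line_width=100.0, seed=11)
    return synth.generate_pattern_image(spec)


@pytest.fixture(scope="session")
def control_image():
    spec = synth.ImageSpec("random", image_size=1024, pixel_pitch=5.0,
                           background_fraction=0.05, line_width=100.0, seed=12)
    return synth.generate_random_image(spec)


@pytest.fixture(scope="session")
def small_proteome():
    """Programmed proteome small enough for fast unit tests."""
    spec = synth.ProteomeSpec(n_proteins=800, n_up=120, n_down=60, seed=21)
    return synth.generate_proteome(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
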