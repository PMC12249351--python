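import numpy as np
import pytest

from wknet.synthetic_xray import BeamConfig, WalnutPhantom, make_scene


@pytest.fixture(scope="session")
def tiny_scene():
    """A small deterministic radiograph with 3 walnuts (shared, read-only)."""
    rng = np.random.default_rng(11)
    img, phantoms = make_scene(rng, 3, class_mix=(0.5, 0.5),
                               canvas=(360, 240), image_id="tiny")
    return img, phantoms


@pytest.fixture(scope="session")
def tiny_items():
    """Eight small labeled radiographs for pipeline tests."""
    rng = np.random.default_rng(23)
    return [
        make_scene(rng, 2, class_mix=(0.5, 0.5), canvas=(300, 200),
                   image_id=f"it{i}")[0]
        for i in range(8)
    ]


@pytest.fixture
def centered_phantom():
    return WalnutPhantom(
        quality_class="accept",
        center=(100.0, 80.0),
        shell_semi_axes=(16.0, 20.0),
        shell_thickness=1.5,
        kernel_fill_fraction=0.9,
        orientation=0.6,
        mm_per_pixel=0.5,
    )


@pytest.fixture
def quiet_beam():
    return BeamConfig(photon_noise_sd=0.0)
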