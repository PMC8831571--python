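import numpy as np
import pytest

import spotgrid as sg


@pytest.fixture(scope="session")
def clean_render():
    """Artifact-free default-design array image at ~14 px pitch."""
    return sg.render_array_image(seed=1)


@pytest.fixture(scope="session")
def clean_registration(clean_render):
    img, _ = clean_render
    return sg.register(img, channel="green")


@pytest.fixture(scope="session")
def tissue_render():
    """Array image with one tissue blob covering part of the lattice."""
    art = sg.ArtifactConfig(tissue=True)
    return sg.render_array_image(artifacts=art, seed=2)


@pytest.fixture(scope="session")
def tissue_registration(tissue_render):
    img, _ = tissue_render
    return sg.register(img, channel="green")


@pytest.fixture(scope="session")
def perfect_lattice():
    """Exact 33x35 lattice point cloud, pitch 14 px, no rotation."""
    cc, rr = np.meshgrid(np.arange(33), np.arange(35))
    cc, rr = cc.ravel(), rr.ravel()
    return np.column_stack([50.0 + cc * 14.0, 60.0 + rr * 14.0])
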