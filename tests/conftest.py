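import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from epidqa import (
    ErrorModel,
    RenderConfig,
    build_lightrad_plan,
    build_picketfence_plan,
    render_lightrad_image,
    render_picketfence_image,
)


@pytest.fixture(scope="session")
def config():
    return RenderConfig()


@pytest.fixture(scope="session")
def picket_plan():
    return build_picketfence_plan()


@pytest.fixture(scope="session")
def picket_image(picket_plan, config):
    """Noiseless nominal picket-fence render shared across tests."""
    return render_picketfence_image(picket_plan, config)


@pytest.fixture(scope="session")
def lightrad_plan():
    return build_lightrad_plan()


@pytest.fixture(scope="session")
def lightrad_image(lightrad_plan, config):
    return render_lightrad_image(lightrad_plan, config, ErrorModel())


def make_image(pixels, spacing=(0.5, 0.5), **kw):
    from epidqa import EPIDImage

    return EPIDImage(pixels=np.asarray(pixels, dtype=float), pixel_spacing_mm=spacing, **kw)
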