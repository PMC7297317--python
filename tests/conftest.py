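import numpy as np
import pytest

from dermabcd import LesionImage, LesionSpec, render_lesion


@pytest.fixture(scope="session")
def circle_fixture():
    """Symmetric circular lesion (alpha = 0) on a 128-px canvas."""
    return render_lesion(LesionSpec(canvas_size=128, shape="circle", radius=35,
                                    noise_sd=2.0, seed=2))


@pytest.fixture(scope="session")
def lopsided_fixture():
    """Strongly asymmetric blob (amplitude 0.5, seed 3)."""
    return render_lesion(LesionSpec(canvas_size=128, shape="blob", radius=30,
                                    asymmetry=0.5, noise_sd=2.0, seed=3))


@pytest.fixture(scope="session")
def circle_lesion(circle_fixture):
    fx = circle_fixture
    return LesionImage(rgb=fx.rgb * fx.mask[..., None], mask=fx.mask)


@pytest.fixture(scope="session")
def lopsided_lesion(lopsided_fixture):
    fx = lopsided_fixture
    return LesionImage(rgb=fx.rgb * fx.mask[..., None], mask=fx.mask)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
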