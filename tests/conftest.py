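import numpy as np
import pytest

from spinepath.synth.slides import render_slide, spec_for_class


@pytest.fixture(scope="session")
def class_slides():
    """One default rendered slide + truth per fracture class."""
    out = {}
    for cls in range(3):
        spec = spec_for_class(cls, seed=100 + cls)
        out[cls] = render_slide(spec)
    return out


@pytest.fixture(scope="session")
def bordered_slide():
    spec = spec_for_class(1, seed=5, background_border_px=32)
    return render_slide(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
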