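import numpy as np
import pytest

from brillmap.mapio import ContrastMap, ShiftMap
from brillmap.phantoms import mature_digit_spec, render_digit_phantom
from brillmap.quantify import to_contrast_map


@pytest.fixture(scope="session")
def mature_spec():
    return mature_digit_spec(seed=11)


@pytest.fixture(scope="session")
def mature_phantom(mature_spec):
    return render_digit_phantom(mature_spec)


@pytest.fixture(scope="session")
def mature_contrast(mature_phantom):
    smap, _ = mature_phantom
    return to_contrast_map(smap)


@pytest.fixture()
def random_shift_map():
    rng = np.random.default_rng(7)
    values = 5.0 + 0.5 * rng.random((40, 74))
    return ShiftMap(values, pixel_um=2.0)


@pytest.fixture()
def small_contrast_map():
    values = np.array([[0.01, 0.02], [0.03, 0.04]])
    return ContrastMap(values, pixel_um=1.0)
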