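import numpy as np
import pytest

from cartigel.composite import (
    composite_curves,
    composite_equilibrium_volume_fraction,
    default_presets,
    matrix_preset,
)


@pytest.fixture(scope="session")
def ph7():
    comp, bath = default_presets(7)
    return comp, bath


@pytest.fixture(scope="session")
def pva1():
    return matrix_preset("pva1")


@pytest.fixture(scope="session")
def pva2():
    return matrix_preset("pva2")


def curve_pair(ph: int, n: int = 200):
    """Composite/filler curve pair on a grid spanning past equilibrium."""
    comp, bath = default_presets(ph)
    h_eq = 1.0 / composite_equilibrium_volume_fraction(comp, bath)
    grid = np.linspace(2.5, 1.15 * h_eq, n)
    return composite_curves(comp, bath, grid)


@pytest.fixture(scope="session")
def ph7_curves():
    return curve_pair(7)


@pytest.fixture(scope="session")
def ph4_curves():
    return curve_pair(4)


@pytest.fixture(scope="session")
def ph1_curves():
    return curve_pair(1)


@pytest.fixture(scope="session")
def fixture_suite(tmp_path_factory):
    from cartigel.simulate import generate_fixture_suite

    out = tmp_path_factory.mktemp("fixtures")
    curves = generate_fixture_suite(seed=123, out_dir=out)
    return curves, out
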