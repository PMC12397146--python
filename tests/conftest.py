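import numpy as np
import pytest

from limnotrends import Hypsography


@pytest.fixture
def cone() -> Hypsography:
    """Conical basin: 1000 m^2 at the surface shrinking to 0 at 10 m."""
    return Hypsography([0.0, 10.0], [1000.0, 0.0])


@pytest.fixture
def cylinder() -> Hypsography:
    """Cylindrical basin: constant 1000 m^2 over 0-10 m."""
    return Hypsography([0.0, 10.0], [1000.0, 1000.0])


@pytest.fixture
def deep_cone() -> Hypsography:
    """Cone down to 24 m, tabulated every metre (study-like depth range)."""
    z = np.arange(0.0, 25.0)
    return Hypsography(z, 134_000.0 * (1.0 - z / 24.0))


@pytest.fixture
def basin() -> Hypsography:
    """Convex (ellipsoid-like) basin to 25 m, 134 000 m^2 surface."""
    z = np.arange(0.0, 26.0)
    return Hypsography(z, 134_000.0 * (1.0 - (z / 25.0) ** 2))
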