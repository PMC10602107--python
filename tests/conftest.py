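import numpy as np
import pytest

from pvshydro import (
    FluidProps,
    lobe_fixture,
    polygon_descriptors,
    sinusoidal_duct,
    solve_section_resistance,
)


def circle_vertices(r: float, n: int = 720) -> np.ndarray:
    th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


def ellipse_vertices(b: float, c: float, n: int = 720) -> np.ndarray:
    th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return np.column_stack([b * np.cos(th), c * np.sin(th)])


@pytest.fixture(scope="session")
def fluid():
    return FluidProps()


@pytest.fixture(scope="session")
def circle_section():
    # area 100 um^2: the typical perivascular cross-section scale
    return polygon_descriptors(circle_vertices(5.642))


@pytest.fixture(scope="session")
def ellipse_section():
    return polygon_descriptors(ellipse_vertices(8.0, 4.0))


@pytest.fixture(scope="session")
def sinusoid_profile():
    # r(z) = 50 + 1.5 sin(2 pi z / 50) over two wavelengths at 0.7 um slices
    return sinusoidal_duct()


@pytest.fixture(scope="session")
def lobe_profiles():
    """Two small lobe fixtures, quantized and smooth variants."""
    out = []
    for seed in (0, 1):
        out.append(
            (
                lobe_fixture(seed, n_sections=8),
                lobe_fixture(seed, n_sections=8, quantize=False),
            )
        )
    return out


@pytest.fixture(scope="session")
def lobe_sun(lobe_profiles, fluid):
    """SUN resistance per section of the quantized lobe fixtures.

    Solved once at a fixed 0.1 um grid (solver error ~0.1%, far below the
    estimator deviations being measured) and shared across tests.
    """
    out = []
    for quant, _smooth in lobe_profiles:
        R = np.array(
            [solve_section_resistance(s, fluid, resolution=0.1).R for s in quant.sections]
        )
        out.append(R)
    return out
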