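import numpy as np
import pytest
import shapely

from ki67score.synthetic import HotSpot, SlideSpec, simulate_slide


@pytest.fixture(scope="session")
def small_slide_spec() -> SlideSpec:
    """A 1.2x1.2 mm slide with one hot spot; fast enough for per-test use."""
    return SlideSpec(
        width_um=1200.0,
        height_um=1200.0,
        base_density_per_mm2=700.0,
        # radius 360 um > the 354 um half-diagonal of a 500 um tile, so the
        # disk fully covers the central tile [500,1000)^2
        hotspots=(HotSpot(750.0, 750.0, 360.0, density_multiplier=4.0, p_positive=0.8),),
        p_base_positive=0.15,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_slide(small_slide_spec):
    """(image, truth, region) tuple shared by imaging/tiling/cli tests."""
    return simulate_slide(small_slide_spec)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)


@pytest.fixture
def unit_square() -> shapely.Polygon:
    return shapely.box(0, 0, 1000, 1000)
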