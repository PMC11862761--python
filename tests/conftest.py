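import numpy as np
import pytest

from vesselgame import RunConfig, generate_scene, make_level_spec
from vesselgame.scene import Point, Scene, VesselPath, Marker, stroke_polygon


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def config():
    return RunConfig()


@pytest.fixture(scope="session")
def scenes_by_level():
    """One deterministic scene per level, shared across tests."""
    return {lvl: generate_scene(make_level_spec(lvl), seed=100 + lvl) for lvl in range(1, 8)}


def make_band_scene(y_low: float = 100.0, y_high: float = 120.0,
                    width: float = 400.0, height: float = 300.0) -> Scene:
    """A minimal scene with one straight horizontal vessel band."""
    band_width = y_high - y_low
    yc = (y_low + y_high) / 2.0
    centerline = [Point(0.0, yc), Point(width / 2, yc), Point(width, yc)]
    poly = stroke_polygon(centerline, band_width)
    vessel = VesselPath(centerline=centerline, width=band_width, polygon=poly,
                        is_target=True)
    markers = [
        Marker(center=centerline[0], radius=8.0, is_black=True),
        Marker(center=centerline[-1], radius=8.0, is_black=True),
    ]
    return Scene(width=width, height=height, level_id=1, seed=0,
                 vessels=[vessel], markers=markers, target_index=0)


@pytest.fixture
def band_scene():
    return make_band_scene()
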