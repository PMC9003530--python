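"""Shared fixtures: a reduced-resolution synthetic capture session.

The simulator renders at 320×180 (the sensor's aspect and field of view,
4× fewer pixels per side than the native 1280×720) so the full pipeline
runs in seconds; segmentation filter sizes scale with the raster.
"""

import numpy as np
import pytest

from limbscan.pipeline import simulate_session
from limbscan.synthetic import LimbPhantom, RigLayout, ground_truth_mesh

TEST_WIDTH, TEST_HEIGHT = 320, 180


@pytest.fixture(scope="session")
def layout():
    return RigLayout(width_px=TEST_WIDTH, height_px=TEST_HEIGHT)


@pytest.fixture(scope="session")
def phantom():
    return LimbPhantom()


@pytest.fixture(scope="session")
def phantom_mesh(phantom):
    return ground_truth_mesh(phantom)


@pytest.fixture(scope="session")
def noiseless_session(tmp_path_factory, layout):
    """A complete noiseless synthetic capture directory."""
    ws = tmp_path_factory.mktemp("capture_noiseless")
    return simulate_session(ws, seed=11, layout=layout)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
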