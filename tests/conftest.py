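import numpy as np
import pytest

from uwfvm import synth
from uwfvm.core import Landmarks


@pytest.fixture(scope="session")
def clean_spec():
    """A clean (noise-free, texture-free) default eye specification."""
    return synth.spec_for_grade("C1", seed=7, noise_sigma=0.0,
                                tessellation_amplitude=0.0)


@pytest.fixture(scope="session")
def clean_eye(clean_spec):
    """(image, mask, tree) for one clean synthetic eye."""
    tree = synth.grow_vessel_tree(clean_spec)
    image, mask = synth.render_fundus(tree, clean_spec)
    return image, mask, tree


@pytest.fixture(scope="session")
def noisy_eye():
    spec = synth.spec_for_grade("C2", seed=11)
    tree = synth.grow_vessel_tree(spec)
    image, mask = synth.render_fundus(tree, spec)
    return image, mask, tree


@pytest.fixture
def horizontal_axis():
    """Reference axis along image columns (macula left of disc)."""
    return Landmarks(disc_center=(100.0, 180.0), macula_center=(100.0, 60.0),
                     fov_center=(100.0, 120.0), fov_radius=110.0)


def draw_line(shape, start, angle_deg, length):
    """Rasterize a 1-px straight line; angle measured from the column axis."""
    canvas = np.zeros(shape, dtype=bool)
    t = np.linspace(0.0, length, int(length * 2) + 1)
    rad = np.deg2rad(angle_deg)
    rows = np.round(start[0] + t * np.sin(rad)).astype(int)
    cols = np.round(start[1] + t * np.cos(rad)).astype(int)
    keep = ((rows >= 0) & (rows < shape[0]) & (cols >= 0) & (cols < shape[1]))
    canvas[rows[keep], cols[keep]] = True
    return canvas
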