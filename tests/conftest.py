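import numpy as np
import pytest
from hypothesis import settings

from ricegrid.scene import SceneSpec, render_scene

settings.register_profile("deterministic", deadline=None, derandomize=True)
settings.load_profile("deterministic")


def grid_positions_cm(rows, cols, pd_cm=30.0, rd_cm=20.0, margin_cm=18.0):
    """Ground positions (x_cm, y_cm) of a rows x cols planting grid."""
    xs = margin_cm + pd_cm * np.arange(cols)
    ys = margin_cm + rd_cm * np.arange(rows)
    xx, yy = np.meshgrid(xs, ys)
    return np.column_stack([xx.ravel(), yy.ravel()])


def make_scene_spec(rows=3, cols=3, seed=7, **kwargs):
    pos = grid_positions_cm(rows, cols)
    width = int((pos[:, 0].max() + 18.0) / 0.2)
    height = int((pos[:, 1].max() + 18.0) / 0.2)
    return SceneSpec(width=width, height=height, positions_cm=pos, seed=seed, **kwargs)


@pytest.fixture(scope="session")
def scene_3x3():
    """A 3x3-cluster rendered scene with its ground truth (seeded)."""
    spec = make_scene_spec()
    img, gt = render_scene(spec)
    return spec, img, gt
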