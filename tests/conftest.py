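import numpy as np
import pytest

from slidetiler.synthetic import SyntheticSlideSpec, generate_slide


@pytest.fixture
def small_slide(tmp_path):
    """A 1024x768 3-level pyramid with 7 blue + 3 brown discs (positivity 30%)."""
    spec = SyntheticSlideSpec(
        width=1024, height=768, n_blue=7, n_brown=3, object_radius=12, seed=11
    )
    path = tmp_path / "small.tif"
    truth = generate_slide(spec, path)
    return path, spec, truth


@pytest.fixture
def slide_folder(tmp_path):
    """A folder with two small synthetic slides and their ground truths."""
    folder = tmp_path / "slides"
    folder.mkdir()
    truths = {}
    for name, seed, n_blue, n_brown in [("a.tif", 3, 5, 5), ("b.tif", 4, 8, 2)]:
        spec = SyntheticSlideSpec(
            width=640, height=480, n_blue=n_blue, n_brown=n_brown,
            object_radius=10, seed=seed, n_levels=2,
        )
        truths[name] = generate_slide(spec, folder / name)
    return folder, truths


def brute_force_cover_counts(width, height, grid):
    """Independent per-pixel tile-cover counter used as the grid oracle."""
    counts = np.zeros((height, width), dtype=np.int32)
    for t in grid:
        counts[t.y_origin : t.y_origin + t.height, t.x_origin : t.x_origin + t.width] += 1
    return counts
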