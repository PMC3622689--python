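import numpy as np
import pytest

from ivpharm import SceneSpec, generate_movie


@pytest.fixture(scope="session")
def dense_scene():
    """A dense 50-cell field with heterogeneous brightness (default spec)."""
    spec = SceneSpec(n_cells=50, field_size=256, brightness_range=(0.3, 1.0), noise_sigma=0.01, seed=7)
    stack, truth = generate_movie(spec)
    return spec, stack, truth


@pytest.fixture(scope="session")
def pk_movie():
    """A 97-frame movie (~2 h at 75 s/frame) with known uptake kinetics."""
    spec = SceneSpec(n_cells=40, field_size=224, n_frames=97, noise_sigma=0.01, seed=3)
    stack, truth = generate_movie(spec)
    return spec, stack, truth


def regions_from_truth(label_map):
    """LabeledRegions built directly from a ground-truth label map."""
    from ivpharm.segmentation import LabeledRegions, Region

    ids = np.unique(label_map)
    ids = ids[ids > 0]
    regions = [
        Region(
            id=int(i),
            area_px=int((label_map == i).sum()),
            centroid=(0.0, 0.0),
            border_pixels=np.empty((0, 2), int),
        )
        for i in ids
    ]
    return LabeledRegions(label_map=label_map, regions=regions)
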