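import numpy as np
import pytest

import lysoclust as lc
from lysoclust.synthgen import Cell, SceneSpec, SceneTruth, Vesicle


def toy_truth(disks, image_shape=(64, 64), cell_id=1):
    """SceneTruth with one square cell and hand-placed disks (y, x, r)."""
    h, w = image_shape
    poly = np.array([[1, 1], [1, w - 2], [h - 2, w - 2], [h - 2, 1]], float)
    cell = Cell(cell_id, poly, (h / 2, w / 2), (h / 2, w / 2), 5.0,
                min(h, w) / 2 - 1)
    vesicles = [Vesicle(i + 1, (y, x), r, cell_id, None)
                for i, (y, x, r) in enumerate(disks)]
    spec = SceneSpec(image_shape=image_shape, n_cells=1,
                     vesicles_per_cell=max(len(disks), 1))
    zeros = np.zeros(image_shape, dtype=np.uint16)
    return SceneTruth(spec=spec, cells=[cell], vesicles=vesicles,
                      cell_mask=zeros + cell_id, nucleus_mask=zeros,
                      vesicle_mask=zeros)


def brute_force_adjacency(mask, expand_px):
    """All-pairs minimum-Chebyshev-distance contact oracle."""
    import itertools

    thresh = 2 * expand_px if expand_px > 0 else 1
    labels = np.unique(mask[mask > 0])
    coords = {lab: np.argwhere(mask == lab) for lab in labels}
    edges = set()
    for a, b in itertools.combinations(labels, 2):
        pa, pb = coords[a], coords[b]
        d = np.abs(pa[:, None, :] - pb[None, :, :]).max(axis=2).min()
        if d <= thresh:
            edges.add((int(a), int(b)))
    return edges


def random_label_mask(rng, shape=(48, 48), n_blobs=8):
    """Random non-overlapping-ish blob labels for adjacency stress tests."""
    mask = np.zeros(shape, dtype=np.int32)
    lab = 0
    for _ in range(n_blobs):
        r = int(rng.integers(1, 4))
        y = int(rng.integers(r, shape[0] - r))
        x = int(rng.integers(r, shape[1] - r))
        yy, xx = np.mgrid[:shape[0], :shape[1]]
        blob = (yy - y) ** 2 + (xx - x) ** 2 <= r ** 2
        if (mask[blob] > 0).any():
            continue
        lab += 1
        mask[blob] = lab
    return mask


@pytest.fixture(scope="session")
def dispersed_clean():
    """Noise-free 4-cell dispersed scene plus its rendered image."""
    spec = lc.preset_spec("dispersed", n_cells=4, seed=7, noise=lc.NOISE_OFF)
    truth = lc.make_scene(spec, "exp1", "control")
    return truth, lc.render_scene(truth)


@pytest.fixture(scope="session")
def clustered_clean():
    spec = lc.preset_spec("clustered", n_cells=4, seed=3, noise=lc.NOISE_OFF)
    truth = lc.make_scene(spec, "exp1", "treated")
    return truth, lc.render_scene(truth)
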