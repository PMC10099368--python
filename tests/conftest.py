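import numpy as np
import pytest

from uwdet.data import save_image, save_labels
from uwdet.scenes import SceneSpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """A small synthetic dataset shared across tests (16 train / 8 val)."""
    root = tmp_path_factory.mktemp("synth")
    spec = SceneSpec(size=96, n_objects=(1, 4), seed=11)
    train, val = generate_dataset(spec, 16, 8, root)
    return root, train, val


@pytest.fixture
def crafted_mosaic_dataset(tmp_path):
    """Four 64x64 single-color images, each with one centered box, for
    hand-enumerable mosaic bookkeeping."""
    from uwdet.data import DatasetManifest, LabelRecord
    pairs = []
    (tmp_path / "images/train").mkdir(parents=True)
    (tmp_path / "labels/train").mkdir(parents=True)
    for i in range(4):
        img = np.full((64, 64, 3), 0.2 + 0.2 * i)
        ip = tmp_path / f"images/train/im{i}.png"
        lp = tmp_path / f"labels/train/im{i}.txt"
        save_image(ip, img)
        save_labels(lp, [LabelRecord(i, 0.5, 0.5, 0.25, 0.25)])
        pairs.append((ip, lp))
    return DatasetManifest(split="train", pairs=pairs,
                           class_names=["a", "b", "c", "d"])
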