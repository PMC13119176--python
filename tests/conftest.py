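import numpy as np
import pytest

from calmaug import Annotation, DatasetItem, DetectionDataset


def make_dataset(per_image_boxes, num_classes=None, image_size=64, seed=0):
    """Build an in-memory dataset from lists of (class_id, cx, cy, w, h) tuples."""
    rng = np.random.default_rng(seed)
    items = []
    max_cid = -1
    for i, boxes in enumerate(per_image_boxes):
        anns = [Annotation(*b) for b in boxes]
        max_cid = max([max_cid] + [a.class_id for a in anns])
        img = rng.integers(0, 256, (image_size, image_size, 3), dtype=np.uint8)
        items.append(DatasetItem(f"img_{i:04d}", anns, image=img))
    k = num_classes if num_classes is not None else max_cid + 1
    return DetectionDataset(items, [f"class_{j}" for j in range(max(k, 1))])


@pytest.fixture(scope="session")
def small_fixture():
    """Small generated leaf/lesion fixture shared across tests."""
    from calmaug import FixtureSpec, generate_dataset

    return generate_dataset(
        FixtureSpec(class_counts=(14, 9, 5, 2), image_size=128, seed=11)
    )
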