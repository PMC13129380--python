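import numpy as np
import pytest

from qcmil import Bag, Cohort


def make_bag(bag_id, features, qualities=None, cell_labels=None, label=0):
    features = np.asarray(features, dtype=float)
    K = features.shape[0]
    if qualities is None:
        qualities = np.full(K, 0.8)
    if cell_labels is None:
        cell_labels = ["unknown"] * K
    return Bag(
        bag_id=bag_id,
        features=features,
        qualities=np.asarray(qualities, dtype=float),
        cell_labels=list(cell_labels),
        patch_ids=[f"{bag_id}-p{i}" for i in range(K)],
        label=label,
    )


@pytest.fixture
def tiny_cohort():
    rng = np.random.default_rng(7)
    bags = [
        make_bag("b0", rng.normal(size=(4, 3)), [0.9, 0.5, 0.2, 0.7],
                 ["normal", "abnormal", "unknown", "normal"], label=1),
        make_bag("b1", rng.normal(size=(2, 3)), [0.6, 0.8],
                 ["normal", "normal"], label=0),
    ]
    return Cohort(bags=bags, C=2, M=3, split_tag="train")
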