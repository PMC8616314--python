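import warnings

import numpy as np
import pytest

from rfomics.feature_io import FeatureTable, ModalityBundle

warnings.filterwarnings("ignore", message="zero-variance")


def make_bundle(n=40, m=6, p=2, delta=1.5, seed=0, modality_ids=None,
                informative=None):
    """Small labelled bundle: class shifts the first `informative`
    features of every modality by `delta`."""
    rng = np.random.default_rng(seed)
    labels = np.repeat([0, 1], n // 2)
    if informative is None:
        informative = m // 2
    if modality_ids is None:
        modality_ids = [f"M{k}" for k in range(p)]
    sample_ids = [f"s{i}" for i in range(n)]
    feature_names = [f"f{j}" for j in range(m)]
    tables = []
    for mid in modality_ids:
        values = rng.standard_normal((n, m))
        values[:, :informative] += delta * labels[:, None]
        tables.append(FeatureTable(mid, sample_ids, feature_names, values,
                                   labels=labels))
    return ModalityBundle(tables), labels


@pytest.fixture
def small_bundle():
    return make_bundle()


@pytest.fixture
def tiny_table():
    return FeatureTable(
        modality_id="T1WI",
        sample_ids=["a", "b"],
        feature_names=["f1", "f2"],
        values=np.array([[1.0, 2.0], [3.0, 4.0]]),
        labels=np.array([0, 1]),
    )
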