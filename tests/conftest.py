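import numpy as np
import pandas as pd
import pytest

from sounddissim import (
    FeatureTable,
    SynthConfig,
    build_stimulus_set,
    extract_features,
    standardize_clip,
)

DEFAULT_SEED = 7


@pytest.fixture(scope="session")
def stimulus_set():
    return build_stimulus_set(SynthConfig(), seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def standardized_set(stimulus_set):
    import copy

    ss = copy.copy(stimulus_set)
    ss.clips = [standardize_clip(c) for c in stimulus_set.clips]
    return ss


@pytest.fixture(scope="session")
def feature_table(standardized_set):
    return extract_features(standardized_set.clips,
                            standardized_set.categories)


def make_synthetic_features(n_items: int = 12, seed: int = 0,
                            categories=None) -> FeatureTable:
    """Small random feature table (no audio) for analysis-level tests."""
    from sounddissim.features import SCALAR_FEATURES

    rng = np.random.default_rng(seed)
    items = [f"item{i:02d}" for i in range(n_items)]
    scalars = pd.DataFrame(
        rng.random((n_items, len(SCALAR_FEATURES))), index=items,
        columns=SCALAR_FEATURES,
    )
    vectors = {
        "cochleagram_median": rng.random((n_items, 8)),
        "cochleagram_iqr": rng.random((n_items, 8)),
        "mps": rng.random((n_items, 10)),
    }
    if categories is None:
        cats = ["vocal", "instrument", "environmental"]
        categories = {it: cats[i % 3] for i, it in enumerate(items)}
    return FeatureTable(scalars, vectors, categories)
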