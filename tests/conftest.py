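"""Shared fixtures: one small synthetic case, its feature stack, a sparse
annotation mask and a trained forest, all session-scoped so the expensive
filter-bank and training work happens once."""

from __future__ import annotations

import numpy as np
import pytest

from naevoscreen.classifier import ForestConfig, train_frf
from naevoscreen.features import build_feature_stack
from naevoscreen.synthetic import SyntheticSpec, generate_case

SMALL_GEOMETRY = dict(width=256, height=160, microns_per_pixel=2.5)


def sparse_labels(truth_mask: np.ndarray, per_class: int, seed: int) -> np.ndarray:
    """Subsample a dense truth mask to a sparse annotation mask."""
    rng = np.random.default_rng(seed)
    sparse = np.zeros_like(truth_mask)
    flat = truth_mask.ravel()
    for label in (1, 2):
        idx = np.flatnonzero(flat == label)
        take = rng.choice(idx, min(per_class, idx.size), replace=False)
        sparse.ravel()[take] = label
    return sparse


@pytest.fixture(scope="session")
def small_case():
    """256x160 synthetic lesion, 25% anomalous area, 200 px scale bar."""
    return generate_case(
        SyntheticSpec(**SMALL_GEOMETRY, anomalous_fraction=0.25, seed=11)
    )


@pytest.fixture(scope="session")
def small_stack(small_case):
    return build_feature_stack(small_case.image)


@pytest.fixture(scope="session")
def sparse_mask(small_case):
    return sparse_labels(small_case.truth_mask, per_class=500, seed=11)


@pytest.fixture(scope="session")
def trained_model(small_stack, sparse_mask):
    return train_frf(small_stack, sparse_mask, ForestConfig(n_trees=50, seed=11))


def random_feature_stack(height, width, n_features, seed):
    """Feature stack of pure noise for classifier-contract tests."""
    from naevoscreen.features import FeatureStack

    rng = np.random.default_rng(seed)
    return FeatureStack(
        values=rng.normal(size=(height, width, n_features)).astype(np.float32),
        channel_names=tuple(f"f{i}" for i in range(n_features)),
    )
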