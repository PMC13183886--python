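"""Shared fixtures: small synthetic tables and a fast test-scale config.

The test-scale configuration shrinks the forest and fold count (and the
squirrel population/iteration budget where a full run is exercised) so the
wrapper remains cheap; scientific thresholds under test are never relaxed.
"""

import numpy as np
import pytest

from issoselect import (
    Dataset,
    PipelineConfig,
    Preprocessor,
    SyntheticSpec,
    generate,
)
from issoselect.config import ForestConfig, ISSOConfig, PreprocessConfig
from issoselect.dataio import categorical, numeric


def fast_config(seed: int = 0, **optimizer_kwargs) -> PipelineConfig:
    opt = dict(n_squirrels=8, n_iterations=6, season_interval=3, seed=seed)
    opt.update(optimizer_kwargs)
    return PipelineConfig(
        optimizer=ISSOConfig(**opt),
        classifier=ForestConfig(n_trees=15),
        preprocessing=PreprocessConfig(),
        cv_folds=3,
        seed=seed,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def toy_dataset():
    """Tiny mixed-kind table with one missing cell."""
    X = np.array([
        [63.0, 1.0, 145.0, 2.3],
        [37.0, 2.0, 130.0, 3.5],
        [41.0, 1.0, np.nan, 1.4],
        [56.0, 1.0, 120.0, 0.8],
        [57.0, 0.0, 140.0, 0.6],
        [63.0, 0.0, 150.0, 2.3],
    ])
    kinds = [numeric(), categorical(0, 1, 2), numeric(), numeric()]
    y = np.array([1, 1, 0, 0, 1, 0])
    return Dataset(X, ["age", "cp", "trestbps", "oldpeak"], kinds, y)


@pytest.fixture(scope="session")
def planted_small():
    """Separable-ish 6-predictor table with 2 planted features, preprocessed."""
    spec = SyntheticSpec(
        n=150, m=6, informative=(0, 1), effects=(1.5, -1.2),
        categorical_levels={4: 3}, prevalence=0.5, seed=11,
    )
    data = generate(spec)
    return Preprocessor().fit_transform(data), spec


@pytest.fixture(scope="session")
def small_forest(planted_small):
    """A small fitted forest plus its data, for explanation tests."""
    from issoselect import train_forest

    proc, _spec = planted_small
    clf = train_forest(proc.features, proc.target, fast_config(), seed=5)
    return clf, proc
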