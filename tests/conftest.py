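import numpy as np
import pytest

from embryopt import anfis, pipeline, simulate


@pytest.fixture(scope="session")
def default_dataset():
    """The seed-42 default synthetic dataset (1080 rows)."""
    return simulate.generate(simulate.GeneratorConfig(seed=42))


@pytest.fixture(scope="session")
def default_split(default_dataset):
    return pipeline.split(default_dataset, 0.75, seed=0)


@pytest.fixture(scope="session")
def trained_models(default_split):
    """One trained model per output on the default 810-row train split."""
    train, _ = default_split
    X = train[simulate.FEATURES].to_numpy()
    models = {}
    for name in simulate.RESPONSES:
        model, _ = anfis.fit(
            X, train[name].to_numpy(), input_names=simulate.FEATURES, output_name=name
        )
        models[name] = model
    return models


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_anfis(rng, n_rules=4, dim=3):
    """A small random-but-valid model for forward-pass oracle tests."""
    rules = [
        anfis.FuzzyRule(
            centers=rng.uniform(0, 1, dim),
            sigmas=rng.uniform(0.1, 0.8, dim),
            consequent=rng.normal(0, 2, dim + 1),
        )
        for _ in range(n_rules)
    ]
    ranges = np.stack([np.zeros(dim), np.ones(dim)], axis=1)
    return anfis.AnfisModel(
        rules, [f"x{i}" for i in range(dim)], "y", input_ranges=ranges
    )
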