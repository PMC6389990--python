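import numpy as np
import pandas as pd
import pytest

from semdecode import (
    CoordinateModel,
    FeatureNorms,
    GenerationConfig,
    KeywordMap,
    SemanticSpace,
    design_matrix,
    generate_dataset,
)


@pytest.fixture(scope="session")
def tiny_config():
    """8 targets, 16-dim space, 8^3 grid: fast but structurally complete."""
    return GenerationConfig(
        items_per_category=2,
        dim=16,
        grid_shape=(8, 8, 8),
        n_informative=40,
        nonclue_features_per_target=4,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return generate_dataset(tiny_config, n_subjects=1)


@pytest.fixture(scope="session")
def noise_free_dataset():
    cfg = GenerationConfig(
        items_per_category=2,
        dim=16,
        grid_shape=(8, 8, 8),
        n_informative=40,
        nonclue_features_per_target=4,
        noise_sd=0.0,
        seed=13,
    )
    return generate_dataset(cfg, n_subjects=1)


def dataset_views(dataset):
    """(targets, categories, reps[T x R x V], Y_avg_allfeat) for a dataset."""
    trials = dataset.trials
    targets = dataset.norms.targets
    categories = [
        dataset.norms.table.loc[dataset.norms.table["target"] == t, "category"].iloc[0]
        for t in targets
    ]
    n_reps = len(trials) // len(targets)
    order = np.concatenate(
        [np.flatnonzero((trials["target"] == t).to_numpy()) for t in targets]
    )
    reps = dataset.beta_stacks[0].betas[order].reshape(len(targets), n_reps, -1)
    Y = design_matrix(
        trials,
        CoordinateModel.ALL_FEATURES,
        dataset.norms,
        dataset.keyword_map,
        dataset.space,
        averaged=True,
    )
    return targets, categories, reps, Y


@pytest.fixture(scope="session")
def toy_norms():
    """Five targets with hand-enumerable feature structure; target 'e' has
    all of its features flagged as clues."""
    rows = []
    for t, (n_clue, n_non) in zip("abcde", [(9, 3), (9, 2), (9, 1), (9, 4), (9, 0)]):
        for j in range(n_clue + n_non):
            rows.append(
                {
                    "target": t,
                    "category": "cat1" if t in "abc" else "cat2",
                    "feature": f"{t}-feat-{j}",
                    "rank": j + 1,
                    "is_clue": j < n_clue,
                }
            )
    return FeatureNorms(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def toy_space_and_map(toy_norms):
    rng = np.random.default_rng(42)
    vectors, mapping = {}, {}
    for t in toy_norms.targets:
        vectors[t] = rng.normal(size=4)
        mapping[t] = t
        for f in toy_norms.features(t):
            token = f.replace("-", "_")
            vectors[token] = rng.normal(size=4)
            mapping[f] = token
    return SemanticSpace(vectors=vectors, dim=4), KeywordMap(mapping)
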