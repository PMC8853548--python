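import numpy as np
import pandas as pd
import pytest

from mbnoise import FeatureTable, SampleMetadata, SimulationConfig, simulate_dataset


@pytest.fixture
def toy_counts():
    return FeatureTable(
        sample_ids=["s1", "s2", "s3"],
        feature_ids=["fA", "fB"],
        values=np.array([[2.0, 2.0], [1.0, 3.0], [4.0, 0.0]]),
        space="counts",
    )


@pytest.fixture
def toy_metadata():
    return SampleMetadata(
        data=pd.DataFrame(
            {"phenotype": ["case", "control", "case"], "study": ["A", "A", "B"],
             "age": [30.0, 40.0, 50.0]},
            index=["s1", "s2", "s3"],
        ),
        column_types={"phenotype": "categorical", "study": "categorical", "age": "continuous"},
        phenotype_col="phenotype",
        batch_col="study",
    )


@pytest.fixture
def random_positive_table():
    rng = np.random.default_rng(0)
    vals = rng.dirichlet(np.ones(12), size=20)
    return FeatureTable(
        sample_ids=[f"s{i}" for i in range(20)],
        feature_ids=[f"f{j}" for j in range(12)],
        values=vals,
        space="relative",
    )


@pytest.fixture(scope="session")
def two_study_dataset():
    cfg = SimulationConfig(
        n_studies=2, samples_per_study=30, n_features=100, bias_sd=1.0,
        n_differential=10, sample_noise_sd=0.5,
    )
    return simulate_dataset(cfg, seed=17)


def make_table(values, space="generic", prefix=("s", "f")):
    values = np.asarray(values, float)
    return FeatureTable(
        sample_ids=[f"{prefix[0]}{i}" for i in range(values.shape[0])],
        feature_ids=[f"{prefix[1]}{j}" for j in range(values.shape[1])],
        values=values,
        space=space,
    )
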