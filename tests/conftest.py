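import numpy as np
import pytest

import consensusvs as cvs
from consensusvs.curation import standardize
from consensusvs.modeling import features_for


@pytest.fixture(scope="session")
def small_config():
    return cvs.SyntheticConfig(n_actives=120, n_inactives=120, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    records, _ = cvs.generate_dataset(small_config)
    dataset, _ = cvs.build_dataset(records, "train")
    return dataset


@pytest.fixture(scope="session")
def small_morgan(small_dataset):
    return features_for(small_dataset, "morgan")


@pytest.fixture(scope="session")
def knn_model(small_dataset, small_morgan):
    spec = cvs.ModelSpec.create(
        "KNN", "morgan", {"n_neighbors": 5, "weight": "distance"}, seed=1
    )
    return cvs.train(spec, small_dataset, features=small_morgan)


@pytest.fixture(scope="session")
def rf_model(small_dataset, small_morgan):
    spec = cvs.ModelSpec.create(
        "RF", "morgan", {"max_features": "sqrt", "n_estimators": 100}, seed=1
    )
    return cvs.train(spec, small_dataset, features=small_morgan)


@pytest.fixture(scope="session")
def consensus_model(knn_model, rf_model):
    return cvs.ConsensusModel(members=[knn_model, rf_model])


@pytest.fixture(scope="session")
def screening_library(small_config):
    entries, truth = cvs.generate_screening_library(
        small_config, n_library=200, hit_fraction=0.2
    )
    compounds = [standardize(smi, cid) for cid, smi in entries]
    return compounds, truth


@pytest.fixture(scope="session")
def balanced400():
    """The y-randomization study conditions: balanced n=400, fixed seed."""
    config = cvs.SyntheticConfig(n_actives=200, n_inactives=200, seed=7)
    records, _ = cvs.generate_dataset(config)
    dataset, _ = cvs.build_dataset(records, "train")
    return dataset, features_for(dataset, "morgan")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
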