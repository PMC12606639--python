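import numpy as np
import pytest
from rdkit import RDLogger

from amesqsar.featurize import compute_features
from amesqsar.neuralnet import NetworkConfig, cross_validate
from amesqsar.synthetic import PlantedLibrarySpec, generate_planted_dataset

RDLogger.DisableLog("rdApp.*")


@pytest.fixture(scope="session")
def planted600():
    """Planted-rule library at the standard study condition: n=600, 5% noise."""
    spec = PlantedLibrarySpec(n=600, positive_fraction=0.5, label_noise=0.05, seed=7)
    ds, truth = generate_planted_dataset(spec)
    return ds, truth


@pytest.fixture(scope="session")
def maccs600(planted600):
    ds, _ = planted600
    return compute_features(ds, "MACCS")


@pytest.fixture(scope="session")
def planted_cv_report(planted600, maccs600):
    """10-fold CV of the selected architecture on the planted fixture."""
    ds, _ = planted600
    cfg = NetworkConfig(seed=3)
    return cross_validate(maccs600, ds.labels(), cfg, k=10, seed=5)


@pytest.fixture(scope="session")
def small_planted():
    """Smaller, faster library for unit-level checks."""
    spec = PlantedLibrarySpec(n=120, positive_fraction=0.5, label_noise=0.0, seed=13)
    ds, truth = generate_planted_dataset(spec)
    return ds, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
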