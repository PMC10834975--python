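import logging

import numpy as np
import pandas as pd
import pytest

from mirflux.config import AnalysisConfig
from mirflux.simulate import GeneratorConfig, generate, write_fixture

logging.getLogger("mirflux").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def cfg():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def dataset():
    """One default-parameter synthetic dataset shared across tests."""
    return generate(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, dataset):
    d = tmp_path_factory.mktemp("fixture")
    write_fixture(dataset, d, force=True)
    return d


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_te_frames(calls_e, calls_t, tissues=("Neu", "Int", "BWM", "Hyp", "Coel"), ages=("D1", "D8")):
    """Boolean E/T tables from {mature: {(tissue, age): bool}} dicts."""
    matures = sorted(set(calls_e) | set(calls_t))
    cols = pd.MultiIndex.from_product([tissues, ages], names=["tissue", "age"])
    E = pd.DataFrame(False, index=matures, columns=cols)
    T = pd.DataFrame(False, index=matures, columns=cols)
    for m, d in calls_e.items():
        for key, v in d.items():
            E.loc[m, key] = v
    for m, d in calls_t.items():
        for key, v in d.items():
            T.loc[m, key] = v
    return E, T
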