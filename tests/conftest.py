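import numpy as np
import pytest

from neuralfp import predictor, synthetic_data
from neuralfp.chem_io import parse_molecule


@pytest.fixture(scope="session")
def corpus():
    """Default synthetic study corpus: 400 molecules, 5 motif-driven ADRs."""
    spec = synthetic_data.SyntheticSpec(seed=1)
    mols, labels, truth = synthetic_data.generate_corpus(spec)
    return mols, labels, truth


@pytest.fixture(scope="session")
def trained_model(corpus):
    """End-to-end model for the first planted ADR, default configuration."""
    mols, labels, _truth = corpus
    config = predictor.TrainConfig(seed=1)
    return predictor.train_adr_model(mols, labels.y[:, 0], config)


@pytest.fixture(scope="session")
def small_molecules():
    return [parse_molecule(s) for s in ["CCO", "c1ccccc1", "CC(=O)N", "C", "CC"]]


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
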