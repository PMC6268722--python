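import numpy as np
import pytest
from rdkit import Chem

from qsarkit.synthetic import (assign_activities, example_scaffolds,
                               example_true_model, generate_dataset)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_mols():
    smiles = ["c1ccncc1", "CCCC", "CCO", "c1ccccc1", "CC(=O)O",
              "Cc1cc2ccc3cc(OC)c(N(C)C)cc3c2cn1", "ClCCN(C)C"]
    return [Chem.MolFromSmiles(s) for s in smiles]


@pytest.fixture(scope="session")
def library42():
    """42 compounds over the six scaffold groups (small, for unit tests)."""
    return generate_dataset(example_scaffolds(), [12, 6, 6, 6, 6, 6], seed=11)


@pytest.fixture(scope="session")
def library42_activity(library42):
    model = example_true_model(noise_sd=0.3)
    return assign_activities(library42, model, seed=3, endpoint="RPMI8402")


@pytest.fixture(scope="session")
def noiseless_library(library42):
    model = example_true_model(noise_sd=0.0)
    acts = assign_activities(library42, model, seed=0)
    return library42, model, acts["activity"].to_numpy()
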