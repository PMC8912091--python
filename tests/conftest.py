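import numpy as np
import pytest

from bcsa.data import SyntheticSpec, generate_synthetic
from bcsa.model import BCSARegressor, ModelConfig

#: A few real drug-like SMILES exercising bracket atoms, aromatic rings,
#: charges and ring labels beyond what the synthetic grammar produces.
DRUG_SMILES = [
    "CC(=O)Oc1ccccc1C(=O)O",  # aspirin
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",  # caffeine
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",  # ibuprofen
    "C[N+](C)(C)CC(=O)[O-]",  # betaine (charged bracket atoms)
    "c1ccc2[nH]ccc2c1",  # indole ([nH])
    "OC[C@H]1OC(O)[C@H](O)[C@@H](O)[C@@H]1O",  # glucose (stereo)
    "Clc1ccc(cc1)C(c1ccccc1)N1CCN(CCOCCO)CC1",  # hydroxyzine-like
    "O=C(O)c1ccccc1O",  # salicylic acid
    "C1CCCCC1",
    "O1CCOCC1",
]


@pytest.fixture(scope="session")
def fixture_smiles() -> list[str]:
    """200 synthetic molecule SMILES plus bracket-heavy drug examples."""
    records = generate_synthetic(
        SyntheticSpec(n_molecules=200, noise_sd=0.0, seed=2024)
    )
    return [r.smiles for r in records] + DRUG_SMILES


@pytest.fixture(scope="session")
def synthetic_records():
    return generate_synthetic(
        SyntheticSpec(n_molecules=60, noise_sd=0.0, seed=7)
    )


@pytest.fixture
def tiny_config() -> ModelConfig:
    return ModelConfig(
        batch_size=8,
        vocab_size=12,
        smiles_max_len=10,
        hidden_size=6,
        num_layers=2,
        dropout=0.0,
        mlp_hidden_size=4,
        learning_rate=0.01,
        embed_dim=5,
        channel_reduction=2,
        seed=11,
    )


@pytest.fixture
def tiny_model(tiny_config) -> BCSARegressor:
    return BCSARegressor(tiny_config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(123)
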