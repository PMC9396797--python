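import numpy as np
import pytest

from rnapairnet.constraints import build_constraint_matrix
from rnapairnet.io import structure_to_pair_matrix
from rnapairnet.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_corpus():
    """60 short constraint-valid records, 30% pseudoknotted."""
    cfg = SyntheticConfig(n=60, length_range=(20, 40), pseudoknot_prob=0.3,
                          pairing_density=0.4, seed=501)
    return generate_dataset(cfg)


def oracle_logits(label: np.ndarray, on: float = 0.9975) -> np.ndarray:
    """Logit matrix whose sigmoid is ~1 on the labelled pairs, ~0 elsewhere."""
    probs = np.where(label == 1, on, 1.0 - on)
    return np.log(probs / (1.0 - probs))


@pytest.fixture
def planted_case(small_corpus):
    seq, structure = small_corpus[0]
    label = structure_to_pair_matrix(structure)
    mask = build_constraint_matrix(seq)
    return seq, structure, label, mask
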