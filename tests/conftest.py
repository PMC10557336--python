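import numpy as np
import pytest

from curvagn.complexes import Atom, MolecularComplex
from curvagn.dataset import featurize_complex
from curvagn.nn.model import ModelConfig, init_state
from curvagn.synthetic import SyntheticSpec, generate_complex


def make_atom(element="C", coord=(0.0, 0.0, 0.0), origin="ligand", **kw):
    return Atom(element=element, coord=np.asarray(coord, float), origin=origin, **kw)


def random_complex(seed: int, noise_sd: float = 0.0, **kw) -> MolecularComplex:
    return generate_complex(SyntheticSpec(seed=seed, noise_sd=noise_sd, **kw))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    """A desk-scale model configuration used throughout the suite."""
    return ModelConfig(
        n_paga_layers=2,
        n_heads=2,
        node_emb_dim=32,
        edge_emb_dim=16,
        curvature_emb_dim=16,
        mlp_hidden=(64, 32),
    )


@pytest.fixture(scope="session")
def sample_and_complex():
    cplx = random_complex(seed=3)
    return featurize_complex(cplx), cplx


@pytest.fixture
def small_state(small_config):
    return init_state(small_config, np.random.default_rng(0))
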