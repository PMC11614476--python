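import numpy as np
import pytest

from pldiffusion.config import RunConfig, TINY
from pldiffusion.fixtures import StubEmbedder, generate_toy_complex
from pldiffusion.model import RedesignModel


@pytest.fixture(scope="session")
def tiny_cfg() -> RunConfig:
    return RunConfig(**TINY)


@pytest.fixture(scope="session")
def embedder(tiny_cfg):
    return StubEmbedder(tiny_cfg.embedder_dim, seed=0)


@pytest.fixture(scope="session")
def toy():
    """8-residue chain with an ethanol ligand (11 tokens)."""
    return generate_toy_complex(8, "CCO", seed=1)


@pytest.fixture()
def model(tiny_cfg, embedder):
    return RedesignModel(tiny_cfg, embedder, seed=3)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-ish random proper rotation via QR."""
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
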