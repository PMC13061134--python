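"""Shared fixtures: small toy complexes and decoy factories."""

import numpy as np
import pytest

from abageval.structure_io import partition_complex
from abageval.synthetic import make_decoy, make_toy_complex


@pytest.fixture(scope="session")
def toy_complex():
    """Two-chain helical complex in contact (antibody H, antigen A)."""
    return make_toy_complex([14, 12], geometry="helix", separation=4.5,
                            seed=11, chain_ids=["H", "A"], target_id="toy")


@pytest.fixture(scope="session")
def toy_partition(toy_complex):
    return partition_complex(toy_complex, ["H"], ["A"])


@pytest.fixture
def decoy_factory(toy_complex, toy_partition):
    """Callable(magnitude, seed, jitter) -> decoy with the antigen group
    translated by a random direction of the given magnitude."""

    def _make(magnitude: float, seed: int = 0, jitter: float = 0.0):
        rng = np.random.default_rng(seed)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        return make_decoy(toy_complex, toy_partition,
                          translation=magnitude * direction,
                          jitter_sigma=jitter, seed=seed + 1)

    return _make


@pytest.fixture(scope="session")
def three_chain_complex():
    """Antibody H plus a two-chain antigen (A, B)."""
    return make_toy_complex([12, 10, 10], geometry="helix", separation=4.5,
                            seed=5, chain_ids=["H", "A", "B"],
                            target_id="toy3")
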