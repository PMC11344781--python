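"""Shared fixtures: small synthetic worlds and toy models, all seeded."""

from __future__ import annotations

import numpy as np
import pytest

from exorigin.motif import MotifModel, packaged_motif
from exorigin.simulate import GeneratorConfig, generate_genome, generate_tags


@pytest.fixture(scope="session")
def acs_motif() -> MotifModel:
    return packaged_motif("ACS")


@pytest.fixture(scope="session")
def b2_motif() -> MotifModel:
    return packaged_motif("B2")


@pytest.fixture(scope="session")
def small_world():
    """A modest planted world shared by read-only tests (100 origins, seed 7)."""
    cfg = GeneratorConfig(n_origins=100, n_chroms=1, seed=7)
    genome, manifest = generate_genome(cfg)
    return genome, manifest


@pytest.fixture(scope="session")
def small_tracks(small_world):
    _, manifest = small_world
    return {
        (p, ph): generate_tags(manifest, p, ph, 80_000, seed=7)
        for p, ph in (("ORC", "G1"), ("ORC", "G2"), ("MCM", "G1"))
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


def random_motif(rng: np.random.Generator, width: int, alpha: float = 0.6) -> MotifModel:
    """A random Dirichlet PWM with a random background (test helper)."""
    mat = rng.dirichlet([alpha] * 4, size=width).T
    bg = rng.dirichlet([5.0] * 4)
    return MotifModel("rand", mat, bg)
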