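"""Shared fixtures: a seeded synthetic corpus, a trained model, and
numerical oracles used by several test modules."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mprap.model import GridSpec, make_cv_split, train
from mprap.synthetic import (
    SyntheticSpec,
    bundle_chain_data,
    generate_complex,
    generate_corpus,
    generate_protein,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

CORPUS_SEED = 1


@pytest.fixture(scope="session")
def spec():
    return SyntheticSpec(seed=CORPUS_SEED)


@pytest.fixture(scope="session")
def small_bundle(spec):
    """One synthetic protein, enough for most unit tests."""
    return generate_protein(spec, 0)


@pytest.fixture(scope="session")
def corpus(spec):
    """The default 40-protein fixture corpus."""
    return generate_corpus(spec)


@pytest.fixture(scope="session")
def chain_data(corpus):
    return [bundle_chain_data(b) for b in corpus]


@pytest.fixture(scope="session")
def cv_split(chain_data):
    return make_cv_split([(c.chain_key, c.family) for c in chain_data],
                         k=5, seed=CORPUS_SEED)


@pytest.fixture(scope="session")
def trained(chain_data, cv_split):
    """Family-grouped 5-fold rbf training on the full corpus (small grid)."""
    return train(chain_data, cv_split, GridSpec.coarse(), kernel="rbf",
                 seed=CORPUS_SEED)


@pytest.fixture(scope="session")
def complexes(spec):
    """Four homodimer fixtures with planted interfaces."""
    return [generate_complex(spec, 100 + i) for i in range(4)]


def mc_sasa(coords, radii, probe, n_points_per_atom, seed=0):
    """Monte-Carlo SASA oracle: uniform points on each atom's
    probe-inflated sphere, rejected if inside any other inflated sphere.

    Independent of the production code path (no Fibonacci lattice, no
    KD-tree)."""
    rng = np.random.default_rng(seed)
    coords = np.asarray(coords, dtype=float)
    inflated = np.asarray(radii, dtype=float) + probe
    total = np.empty(len(coords))
    for i in range(len(coords)):
        pts = rng.normal(size=(n_points_per_atom, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        pts = coords[i] + inflated[i] * pts
        outside = np.ones(n_points_per_atom, dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            outside &= d2 >= inflated[j] ** 2
        total[i] = 4.0 * np.pi * inflated[i] ** 2 * outside.mean()
    return total
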