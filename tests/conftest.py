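"""Shared fixtures: small synthetic datasets built at test time."""

from __future__ import annotations

import numpy as np
import pytest

from finekin import GenotypeMatrix, SpatialFrame


def make_hwe_genotypes(
    rng: np.random.Generator,
    n: int,
    n_loci: int = 3,
    n_alleles: int = 6,
    freqs: list[np.ndarray] | None = None,
) -> GenotypeMatrix:
    """Random-mating genotypes at given (or Dirichlet-drawn) allele freqs."""
    if freqs is None:
        freqs = [rng.dirichlet(np.ones(n_alleles)) for _ in range(n_loci)]
    calls = [
        [
            tuple(sorted(str(a) for a in rng.choice(len(freqs[l]), 2, p=freqs[l])))
            for l in range(n_loci)
        ]
        for _ in range(n)
    ]
    ids = [f"i{j}" for j in range(n)]
    return GenotypeMatrix(ids, [f"L{l + 1}" for l in range(n_loci)], calls)


def make_random_spatial(rng: np.random.Generator, n: int, extent: float = 100.0) -> SpatialFrame:
    return SpatialFrame(
        [f"i{j}" for j in range(n)], rng.random(n) * extent, rng.random(n) * extent
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_240_901)


@pytest.fixture(scope="session")
def two_deme_dataset():
    """A two-deme secondary-contact world with a random 80-tree sample."""
    import finekin as fk

    d = fk.simulate(fk.two_deme_config(seed=0))
    return fk.sample_transect(d, 80, "random", seed=0)


@pytest.fixture(scope="session")
def small_ibd_dataset():
    """A small isolation-by-distance world for end-to-end runs."""
    import finekin as fk

    cfg = fk.SimulationConfig(
        scenario="ibd",
        width=200.0,
        height=200.0,
        cell_size=20.0,
        density=0.01,
        sigma_seed=10.0,
        sigma_pollen=25.0,
        generations=50,
        seed=7,
    )
    d = fk.simulate(cfg)
    return fk.sample_transect(d, 60, "random", seed=7)
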