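"""Shared fixtures: small synthetic systems generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from densfit import (
    AtomicModel,
    DensityMap,
    FixtureSpec,
    SpreadParams,
    make_target_maps,
    make_toy_barrel,
    normalize_map,
)


@pytest.fixture(scope="session")
def barrel_spec() -> FixtureSpec:
    """Small, fast toy barrel: 36 beads in a 32^3 box at 0.84 Å/voxel."""
    return FixtureSpec(n_strands=6, strand_length=6, radius=4.5, box=32,
                       pixel_size=0.84, noise_sd=0.0, seed=1)


@pytest.fixture(scope="session")
def barrel(barrel_spec):
    return make_toy_barrel(barrel_spec)


@pytest.fixture(scope="session")
def barrel_model(barrel):
    return barrel[0]


@pytest.fixture(scope="session")
def barrel_topo(barrel):
    return barrel[1]


@pytest.fixture(scope="session")
def barrel_maps(barrel_model, barrel_spec):
    return make_target_maps(barrel_model, barrel_spec)


@pytest.fixture(scope="session")
def barrel_target(barrel_maps):
    """Normalized noiseless target self-generated from the barrel."""
    return normalize_map(barrel_maps[0])


@pytest.fixture(scope="session")
def spread_params(barrel_spec):
    return SpreadParams.for_pixel_size(barrel_spec.pixel_size)


@pytest.fixture
def random_map():
    rng = np.random.default_rng(42)
    return DensityMap(rng.standard_normal((16, 16, 16)), np.full(3, 1.0))


def random_model(n: int, seed: int, scale: float = 10.0) -> AtomicModel:
    """Helper: n carbon-like atoms uniformly scattered in a cube."""
    rng = np.random.default_rng(seed)
    return AtomicModel(
        coords=rng.uniform(-scale, scale, (n, 3)),
        elements=["C"] * n,
        masses=np.full(n, 12.011),
        amplitudes=np.full(n, 6.0),
        atom_names=["CA"] * n,
        residue_ids=np.arange(1, n + 1),
        chain_ids=["A"] * n,
        is_heavy=np.ones(n, dtype=bool),
    )
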