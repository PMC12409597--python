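"""Shared fixtures: small atlases, planted and null cohorts, reduced grids.

Everything is generated programmatically at collection time; the compact
30-region / nine-network layout keeps single tests in the seconds range
while preserving the full structure (all 45 network-pair cells non-empty
except those involving the 2-region cerebellum's within cell... which has
exactly one edge, so even that is covered).
"""

import numpy as np
import pytest

from connpred import HyperGrid, SyntheticSpec, generate_cohort, make_atlas

SMALL_SIZES = (5, 4, 4, 3, 3, 3, 3, 3, 2)  # 30 regions, 435 edges


@pytest.fixture(scope="session")
def small_atlas():
    return make_atlas(SMALL_SIZES)


@pytest.fixture(scope="session")
def reduced_grid():
    """Single-cell grid: inner search short-circuits, validation is ~20 ms."""
    return HyperGrid.single(0.5, 10)


@pytest.fixture(scope="session")
def planted_small():
    """rho* = 0.5 cohort at reduced scale (n=120, 30 regions)."""
    spec = SyntheticSpec(n_participants=120, network_sizes=SMALL_SIZES, seed=7)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def null_small():
    """No latent factor at all: edges and outcomes are independent noise."""
    spec = SyntheticSpec(
        latent_strength_brain=0.0,
        latent_strength_symptom=0.0,
        group_offset_sd=0.0,
        n_participants=80,
        network_sizes=SMALL_SIZES,
        seed=13,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def noisefree_small():
    """Near-noise-free planted cohort: every cell loaded, tiny residual noise.

    Exactly zero noise would leave unloaded edge columns constant (a hard
    standardization error by design), so all 45 cells are loaded at full
    fraction and the residual SDs are 1e-6.
    """
    atlas = make_atlas(SMALL_SIZES)
    spec = SyntheticSpec(
        n_participants=40,
        network_sizes=SMALL_SIZES,
        loaded_network_pairs=tuple(atlas.all_cells()),
        loading_fraction=1.0,
        edge_noise_sd=1e-6,
        symptom_noise_sd=1e-6,
        group_offset_sd=0.0,
        seed=5,
    )
    return generate_cohort(spec)
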