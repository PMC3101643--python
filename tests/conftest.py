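"""Shared fixtures: toy proteins and the standard two-conformer crystal."""

from dataclasses import dataclass

import numpy as np
import pytest

import densvar as dv
from densvar.density import DensityGrid, GridRegion, density_map, fragment_box


@pytest.fixture(scope="session")
def toy3():
    """3-residue poly-alanine helix (15 atoms)."""
    return dv.make_toy_protein(3, "helix", seed=0)


@pytest.fixture(scope="session")
def toy8():
    return dv.make_toy_protein(8, "helix", seed=0)


@dataclass
class StandardFixture:
    """The paper-protocol synthetic experiment at desk scale, seed 0."""

    crystal: dv.CrystalFixture
    ensemble: dv.Ensemble
    base_map: DensityGrid
    alt_map: DensityGrid
    member_maps: list
    region: GridRegion


def build_standard_fixture(seed: int, n_residues: int = 8, sigma: float = 0.1,
                           n_noise: int = 2, n_variable: int = 2) -> StandardFixture:
    base = dv.make_toy_protein(n_residues, "helix", seed=0)
    alt = dv.sample_neighborhood(base, (0.8, 1.2), 1, seed=seed + 1000)[0]
    crystal = dv.make_two_conformer_crystal(base, alt, d_min=2.0, seed=seed)
    ens = dv.make_labeled_ensemble(
        crystal, n_noise, n_variable, dv.NoiseModel(sigma, seed=seed)
    )
    shape = crystal.mixed_map.shape
    base_map = density_map(crystal.base, crystal.cell, crystal.spacing, shape=shape)
    alt_map = density_map(crystal.alternate, crystal.cell, crystal.spacing, shape=shape)
    member_maps = [
        density_map(m, crystal.cell, crystal.spacing, shape=shape) for m in ens.members
    ]
    residues = crystal.base.residue_indices
    region = fragment_box(
        crystal.base, (int(residues.min()), int(residues.max())), 2.0, base_map
    )
    return StandardFixture(crystal, ens, base_map, alt_map, member_maps, region)


@pytest.fixture(scope="session")
def standard_fixture():
    return build_standard_fixture(seed=0)
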