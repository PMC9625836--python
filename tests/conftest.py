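import numpy as np
import pytest

import trxss


@pytest.fixture(scope="session")
def tiny_spec():
    """Small toy system: 4 helices x 4 residues, 6 detergents, some water."""
    return trxss.ToySystemSpec(n_helices=4, residues_per_helix=4,
                               detergent_count=6, micelle_radius=20.0,
                               water_box=(12.0, 12.0, 12.0), seed=2)


@pytest.fixture(scope="session")
def tiny_system(tiny_spec):
    return trxss.make_toy_system(tiny_spec)


@pytest.fixture(scope="session")
def small_protein():
    """~450 heavy-atom protein-only fragment for scattering oracles."""
    spec = trxss.ToySystemSpec(n_helices=7, residues_per_helix=8,
                               detergent_count=12, micelle_radius=22.0,
                               hydrogens=False, seed=1)
    sys_ = trxss.make_toy_system(spec)
    prot = sys_.by_component("protein")
    return prot.select(prot.res_id <= 64)


@pytest.fixture(scope="session")
def qgrid():
    return np.linspace(0.0, 2.0, 41)


@pytest.fixture(scope="session")
def grid_experiment():
    """Desk-scale synthetic structural-fitting problem (seeded, ~1 min)."""
    return trxss.make_grid_experiment(seed=1)
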