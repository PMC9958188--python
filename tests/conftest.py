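import copy

import numpy as np
import pytest

from rnpscore.decoygen import DecoySpec, generate_decoy_set, generate_toy_complex
from rnpscore.featurize import featurize_structure
from rnpscore.network import NetworkConfig
from rnpscore.structures import (
    assign_types,
    build_canonical_protein_table,
    build_canonical_rna_table,
    load_default_tables,
)


@pytest.fixture(scope="session")
def tables():
    return load_default_tables()


@pytest.fixture(scope="session")
def canonical_rna_table():
    return build_canonical_rna_table()


@pytest.fixture(scope="session")
def canonical_protein_table():
    return build_canonical_protein_table()


@pytest.fixture(scope="session")
def _toy_complex_master():
    return generate_toy_complex(seed=1, n_nt=6, n_aa=8)


@pytest.fixture
def toy_complex(_toy_complex_master):
    # tests mutate (type-annotate) the complex; hand each a fresh copy
    return copy.deepcopy(_toy_complex_master)


@pytest.fixture
def typed_complex(toy_complex, tables):
    rna_table, protein_table = tables
    return assign_types(toy_complex, rna_table, protein_table)


@pytest.fixture(scope="session")
def decoy_set(_toy_complex_master):
    spec = DecoySpec(
        n_decoys=6, rmsd_bins=[(0.5, 4.0, 3), (4.0, 12.0, 3)], seed=7
    )
    return generate_decoy_set(copy.deepcopy(_toy_complex_master), spec)


@pytest.fixture
def tiny_net_config():
    """Cheap configuration for gradient/determinism tests."""
    return NetworkConfig(
        conv_channels=(4, 6), seq_strides=(2, 1), L=4, grid_size=4
    )


@pytest.fixture
def reduced_net_config():
    """The L=8 / 8^3 reduced configuration with the printed channel schedule."""
    return NetworkConfig(L=8, grid_size=8)


def featurize_reduced(complex_, tables, L=8, grid_size=8):
    rna_table, protein_table = tables
    return featurize_structure(
        copy.deepcopy(complex_), rna_table, protein_table, L=L, grid_size=grid_size
    )


def random_rigid(rng):
    """A random proper rotation matrix and translation vector."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.uniform(-20, 20, size=3)
    return Q, t


def transform_complex(complex_, Q, t):
    """Rigidly move every atom of a (copy of a) complex."""
    moved = copy.deepcopy(complex_)
    for units in (moved.rna_units, moved.protein_units):
        for unit in units:
            for atom in unit.atoms:
                atom.position = Q @ atom.position + t
    return moved
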