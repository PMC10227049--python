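import numpy as np
import pytest

from chirsep.chem_graphs import Condition, build_dual_graph, load_column_registry
from chirsep.qgeognn_model import ModelConfig, QGeoGNN

ALANINE_R = "C[C@@H](N)C(=O)O"
ALANINE_S = "C[C@H](N)C(=O)O"


@pytest.fixture(scope="session")
def registry():
    return load_column_registry()


@pytest.fixture(scope="session")
def small_model_config():
    return ModelConfig(num_layers=2, embed_dim=16, multi_column=False)


@pytest.fixture(scope="session")
def small_model(small_model_config):
    return QGeoGNN(small_model_config, seed=7)


@pytest.fixture(scope="session")
def alanine_pair_duals():
    cond = Condition(0.05, 1.0)
    return (
        build_dual_graph(ALANINE_S, cond, seed=1),
        build_dual_graph(ALANINE_R, cond, seed=1),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def _permute_dual_atoms(smiles, condition, perm, seed=0, column=None):
    """DualGraph built from the SAME conformer with atoms renumbered."""
    from rdkit import Chem

    from chirsep.chem_graphs import (
        Conformer3D,
        DualGraph,
        augment_with_column,
        build_atom_bond_graph,
        build_bond_angle_graph,
        compute_descriptors,
        embed_conformer,
    )

    base = embed_conformer(smiles, seed=seed)
    mol_perm = Chem.RenumberAtoms(base.mol, list(perm))
    conf_perm = Conformer3D(
        mol=mol_perm,
        atom_positions=mol_perm.GetConformer(0).GetPositions().astype(float),
        source_seed=base.source_seed,
        smiles=base.smiles,
        explicit_hs=base.explicit_hs,
    )
    desc = compute_descriptors(smiles)
    g = build_atom_bond_graph(conf_perm, condition.elution_proportion)
    h = build_bond_angle_graph(conf_perm, desc)
    dual = DualGraph(g, h, base.smiles, condition, None, desc)
    if column is not None:
        dual = augment_with_column(dual, column)
    return dual
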