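"""Featurization: conformers, dual graphs, descriptors, column augmentation."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from chirsep.chem_graphs import (
    Condition,
    augment_with_column,
    build_atom_bond_graph,
    build_bond_angle_graph,
    build_dual_graph,
    compute_descriptors,
    embed_conformer,
)
from chirsep.errors import (
    ContractError,
    FeaturizationError,
    SmilesParseError,
    StateError,
)
from tests.conftest import ALANINE_R, ALANINE_S

CHIRAL_TAG_COL = 1  # position of the chiral tag among the 9 atom features


def _kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Best rotation-only superposition RMSD (centered), brute-force oracle."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    rot, _ = Rotation.align_vectors(a, b)
    return float(np.sqrt(np.mean(np.sum((a - rot.apply(b)) ** 2, axis=1))))


class TestEmbedConformer:
    def test_water_symmetric_bonds(self):
        conf = embed_conformer("O", seed=0, explicit_hs=True)
        assert conf.atom_positions.shape == (3, 3)
        d = np.linalg.norm(conf.atom_positions[0] - conf.atom_positions[1:], axis=1)
        assert abs(d[0] - d[1]) < 0.05  # two equivalent O-H bonds

    def test_deterministic_for_fixed_seed(self):
        a = embed_conformer(ALANINE_S, seed=3)
        b = embed_conformer(ALANINE_S, seed=3)
        np.testing.assert_array_equal(a.atom_positions, b.atom_positions)
        assert a.source_seed == b.source_seed

    def test_enantiomers_are_mirror_related_not_superimposable(self):
        from rdkit import Chem

        conf_s = embed_conformer(ALANINE_S, seed=2)
        conf_r = embed_conformer(ALANINE_R, seed=2)
        # rotation alone cannot superimpose the two stereoisomers
        assert _kabsch_rmsd(conf_s.atom_positions, conf_r.atom_positions) > 0.2

        def _cip_from_3d(conf, flip=False):
            mol = Chem.Mol(conf.mol)
            if flip:
                c = mol.GetConformer(0)
                for i in range(mol.GetNumAtoms()):
                    p = c.GetAtomPosition(i)
                    c.SetAtomPosition(i, (-p.x, p.y, p.z))
            Chem.AssignStereochemistryFrom3D(mol)
            return Chem.FindMolChiralCenters(mol)[0][1]

        # the 3D geometry carries the handedness of the chiral tags…
        assert _cip_from_3d(conf_s) != _cip_from_3d(conf_r)
        # …and reflecting one conformer flips it onto the other's label
        assert _cip_from_3d(conf_s, flip=True) == _cip_from_3d(conf_r)

    def test_unparseable_smiles_raises(self):
        with pytest.raises(SmilesParseError):
            embed_conformer("not-a-smiles", seed=0)


class TestGraphG:
    def test_ethanol_counts(self):
        g = build_atom_bond_graph(embed_conformer("CCO", seed=0), 0.1)
        assert g.num_atoms == 3          # heavy atoms, implicit-H convention
        assert g.edge_index.shape == (2, 4)  # 2 bonds -> 4 message paths
        assert g.node_features.shape[1] == 9

    def test_every_edge_present_in_both_directions(self):
        g = build_atom_bond_graph(embed_conformer("CC(C)[C@H](O)c1ccccc1", seed=0), 0.05)
        fwd = set(zip(g.edge_index[0], g.edge_index[1]))
        assert all((b, a) in fwd for a, b in fwd)
        assert g.edge_index.max() < g.num_atoms

    def test_proportion_broadcast_and_bounds(self):
        conf = embed_conformer("CCO", seed=0)
        g = build_atom_bond_graph(conf, 0.02)
        np.testing.assert_array_equal(g.edge_features[:, 3], 0.02)
        with pytest.raises(ContractError):
            build_atom_bond_graph(conf, 1.5)

    def test_enantiomers_differ_only_in_chiral_tag_column(self):
        ga = build_atom_bond_graph(embed_conformer(ALANINE_S, seed=1), 0.05)
        gb = build_atom_bond_graph(embed_conformer(ALANINE_R, seed=1), 0.05)
        diff_cols = np.nonzero((ga.node_features != gb.node_features).any(axis=0))[0]
        np.testing.assert_array_equal(diff_cols, [CHIRAL_TAG_COL])
        # edge features (directions, types, ring flags) identical here
        np.testing.assert_array_equal(ga.edge_features, gb.edge_features)


class TestGraphH:
    def test_water_single_angle_pair(self):
        conf = embed_conformer("O", seed=0, explicit_hs=True)
        h = build_bond_angle_graph(conf, compute_descriptors("O"))
        assert h.node_features.shape == (2, 1)
        assert h.edge_index.shape == (2, 2)  # one bond pair, both directions

    def test_methane_angle_pair_count(self):
        conf = embed_conformer("C", seed=0, explicit_hs=True)
        h = build_bond_angle_graph(conf, compute_descriptors("C"))
        assert h.node_features.shape[0] == 4
        assert h.edge_index.shape[1] == 12  # C(4,2)=6 pairs, both directions

    def test_h_edges_join_bonds_sharing_one_atom(self):
        conf = embed_conformer("CC(C)CO", seed=0)
        h = build_bond_angle_graph(conf, compute_descriptors("CC(C)CO"))
        bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in conf.mol.GetBonds()]
        for b1, b2 in zip(h.edge_index[0], h.edge_index[1]):
            shared = set(bonds[b1]) & set(bonds[b2])
            assert len(shared) == 1
        assert np.all(h.edge_features[:, 0] >= 0)
        assert np.all(h.edge_features[:, 0] <= np.pi)

    def test_single_atom_molecule_rejected(self):
        with pytest.raises(FeaturizationError):
            build_bond_angle_graph(embed_conformer("O", seed=0), compute_descriptors("O"))


class TestDescriptors:
    def test_benzene_has_zero_polar_surface(self):
        d = compute_descriptors("c1ccccc1")
        assert d.tpsa == 0.0
        assert d.rpsa == 0.0

    @pytest.mark.parametrize("smiles", ["CCO", ALANINE_S, "c1ccccc1", "C[C@H](O)c1ccccc1"])
    def test_relative_fractions_in_unit_interval(self, smiles):
        d = compute_descriptors(smiles)
        assert np.all(np.isfinite(d.as_array()))
        assert 0.0 <= d.rpsa <= 1.0
        assert 0.0 <= d.rasa <= 1.0

    def test_enantiomers_share_descriptors(self):
        np.testing.assert_array_equal(
            compute_descriptors(ALANINE_S).as_array(),
            compute_descriptors(ALANINE_R).as_array(),
        )


class TestColumnAugmentation:
    def test_widths_grow_to_7_and_11(self, registry):
        dual = build_dual_graph(ALANINE_S, Condition(0.05, 1.0), seed=0)
        aug = augment_with_column(dual, registry["ADH"])
        assert aug.g.edge_features.shape[1] == 7
        assert aug.h.edge_features.shape[1] == 11
        assert not dual.augmented and aug.augmented

    def test_column_codes_broadcast(self, registry):
        dual = build_dual_graph(ALANINE_S, Condition(0.05, 1.0), seed=0)
        ia, adh = registry["IA"], registry["ADH"]  # differ only in connection
        a = augment_with_column(dual, adh)
        b = augment_with_column(dual, ia)
        diff = np.nonzero((a.g.edge_features != b.g.edge_features).any(axis=0))[0]
        np.testing.assert_array_equal(diff, [6])  # connection-code column only

    def test_double_augmentation_rejected(self, registry):
        dual = build_dual_graph(ALANINE_S, Condition(0.05, 1.0), seed=0)
        aug = augment_with_column(dual, registry["ADH"])
        with pytest.raises(StateError):
            augment_with_column(aug, registry["ODH"])


def test_atom_relabeling_permutes_feature_rows():
    """Non-canonical atom order yields the same graph up to row permutation."""
    cond = Condition(0.05, 1.0)
    a = build_dual_graph("CCO", cond, seed=0)
    b = build_dual_graph("OCC", cond, seed=0)
    rows_a = sorted(map(tuple, a.g.node_features))
    rows_b = sorted(map(tuple, b.g.node_features))
    assert rows_a == rows_b
    assert a.g.edge_index.shape == b.g.edge_index.shape
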