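"""Dual-graph featurization of chiral molecules for retention-time models.

A molecule under a chromatographic condition is represented by two
coupled graphs:

* **Graph G** (atom-bond): nodes are atoms with 9 integer-coded
  properties (atomic number, chiral tag, degree, explicit valence,
  formal charge, hybridization, implicit valence, aromaticity, number of
  attached hydrogens); edges are chemical bonds carrying bond direction,
  bond type and ring membership, plus the elution proportion of the
  mobile phase broadcast onto every edge.
* **Graph H** (bond-angle): nodes are G's bonds with the 3D bond length
  as the single node feature; edges join every pair of bonds sharing an
  atom and carry the bond angle together with five molecular
  descriptors (TPSA, RPSA, RASA, MEDC, MATS) broadcast to every edge.

For multi-column models, :func:`augment_with_column` appends the HPLC
column's physical properties to G's edge features (packing size,
substrate, connection type) and the chiral stationary phase's descriptor
vector to H's edge features.

Graphs are plain numpy containers; categorical encoding to one-hot
happens inside the model against the code tables in
:mod:`chirsep.constants`.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Optional

import numpy as np
import yaml
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem, Descriptors, rdMolDescriptors

from . import constants
from .errors import ContractError, FeaturizationError, SmilesParseError, StateError

RDLogger.DisableLog("rdApp.warning")

HYDROPHOBIC_ELEMENTS = {6, 9, 17, 35, 53}  # carbon and halogens
POLAR_ELEMENTS = {7, 8, 15, 16}

# -- containers -----------------------------------------------------------


class Condition(NamedTuple):
    """Mobile-phase condition: minor-component fraction and flow rate (mL/min)."""

    elution_proportion: float
    flow_rate: float


@dataclass(frozen=True)
class Conformer3D:
    """One embedded 3D conformation of a molecule.

    ``mol`` keeps the RDKit molecule whose conformer 0 holds the
    coordinates; ``source_seed`` is the distance-geometry seed that
    produced the embedding, recorded for reproducibility.
    """

    mol: Chem.Mol
    atom_positions: np.ndarray
    source_seed: int
    smiles: str
    explicit_hs: bool


@dataclass
class GraphG:
    node_features: np.ndarray   # [num_atoms, 9] integer codes
    edge_index: np.ndarray      # [2, num_messages] COO
    edge_features: np.ndarray   # [num_messages, 4 or 7]
    edge_bond_ids: np.ndarray   # [num_messages] -> bond index (node of H)

    @property
    def num_atoms(self) -> int:
        return self.node_features.shape[0]

    @property
    def num_bonds(self) -> int:
        return self.edge_index.shape[1] // 2


@dataclass
class GraphH:
    node_features: np.ndarray   # [num_bonds, 1] bond length (Å)
    edge_index: np.ndarray      # [2, num_messages]
    edge_features: np.ndarray   # [num_messages, 6 or 11]

    @property
    def num_bonds(self) -> int:
        return self.node_features.shape[0]


@dataclass(frozen=True)
class DescriptorVector:
    """The five 2D molecular descriptors fed to Graph H.

    tpsa
        Topological polar surface area (Å²).
    rpsa
        Relative polar surface area: Labute ASA contribution of polar
        atoms (N, O, S, P) over the total approximate surface area,
        in [0, 1].
    rasa
        Relative hydrophobic surface area: the Labute ASA contribution
        of carbon and halogen atoms over the total, in [0, 1].
    medc
        Molecular distance-edge statistic over carbon-carbon pairs:
        n_pairs divided by the squared geometric mean of their
        topological distances.
    mats
        Moran spatial autocorrelation of atomic mass at lag 1 on the
        molecular graph.

    All five are constitution-level (2D) quantities, hence identical for
    the two members of an enantiomer pair.
    """

    tpsa: float
    rpsa: float
    rasa: float
    medc: float
    mats: float

    def as_array(self) -> np.ndarray:
        return np.array([self.tpsa, self.rpsa, self.rasa, self.medc, self.mats])


@dataclass(frozen=True)
class ColumnSpec:
    """An HPLC column and its encodable properties."""

    name: str
    substrate_code: int      # 0 = amylose, 1 = cellulose
    connection_code: int     # 0 = immobilized, 1 = coated
    packing_size: float      # μm
    csp_descriptors: np.ndarray  # 5-vector: descriptors of the CSP monomer unit

    def __post_init__(self):
        if self.substrate_code not in (0, 1) or self.connection_code not in (0, 1):
            raise ContractError("substrate/connection codes must be 0 or 1")
        if self.packing_size <= 0:
            raise ContractError("packing_size must be positive")
        object.__setattr__(self, "csp_descriptors", np.asarray(self.csp_descriptors, float))
        if self.csp_descriptors.shape != (5,):
            raise ContractError("csp_descriptors must be a 5-vector")


@dataclass
class DualGraph:
    g: GraphG
    h: GraphH
    smiles: str
    condition: Condition
    column: Optional[ColumnSpec] = None
    descriptors: Optional[DescriptorVector] = None

    @property
    def augmented(self) -> bool:
        return self.g.edge_features.shape[1] == 7


# -- conformer embedding ---------------------------------------------------


def _parse_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"cannot parse SMILES: {smiles!r}")
    return mol


def embed_conformer(
    smiles: str,
    seed: int = 0,
    explicit_hs: bool = False,
    max_tries: int = 5,
) -> Conformer3D:
    """Embed a 3D conformer with distance geometry (ETKDGv3).

    Deterministic for fixed ``(smiles, seed)``; tries ``seed .. seed +
    max_tries - 1`` before failing.  By default hydrogens are added for
    the embedding and then stripped, leaving a heavy-atom graph with
    hydrogen counts as a node feature; ``explicit_hs=True`` keeps them.
    """
    mol = _parse_smiles(smiles)
    molh = Chem.AddHs(mol)
    ok = -1
    for attempt in range(max_tries):
        params = AllChem.ETKDGv3()
        params.randomSeed = int(seed) + attempt
        ok = AllChem.EmbedMolecule(molh, params)
        if ok == 0:
            used_seed = int(seed) + attempt
            break
    if ok != 0:
        raise FeaturizationError(
            f"conformer embedding failed after {max_tries} seeds for {smiles!r}"
        )
    out = molh if explicit_hs else Chem.RemoveHs(molh)
    pos = out.GetConformer(0).GetPositions().astype(np.float64)
    if not np.all(np.isfinite(pos)):
        raise FeaturizationError(f"non-finite conformer coordinates for {smiles!r}")
    return Conformer3D(
        mol=out,
        atom_positions=pos,
        source_seed=used_seed,
        smiles=Chem.MolToSmiles(mol),
        explicit_hs=explicit_hs,
    )


# -- atom and bond feature extraction --------------------------------------


def _atom_features(atom: Chem.Atom) -> list[int]:
    anum = atom.GetAtomicNum()
    anum_code = (
        constants.ATOMIC_NUMS.index(anum)
        if anum in constants.ATOMIC_NUMS
        else constants.ATOMIC_NUM_OTHER
    )
    chiral = min(int(atom.GetChiralTag()), 3)
    charge = int(np.clip(atom.GetFormalCharge(), -2, 2)) + constants.FORMAL_CHARGE_OFFSET
    return [
        anum_code,
        chiral,
        min(atom.GetDegree(), 6),
        min(atom.GetExplicitValence(), 7),
        charge,
        min(int(atom.GetHybridization()), 7),
        min(atom.GetImplicitValence(), 6),
        int(atom.GetIsAromatic()),
        min(atom.GetTotalNumHs(), 4),
    ]


def _bond_features(bond: Chem.Bond) -> list[float]:
    btype = constants.BOND_TYPE_CODES.get(
        bond.GetBondTypeAsDouble(), constants.BOND_TYPE_OTHER
    )
    return [float(int(bond.GetBondDir())), float(btype), float(bond.IsInRing())]


def build_atom_bond_graph(conformer: Conformer3D, elution_proportion: float) -> GraphG:
    """Build Graph G: atoms as nodes, bonds as bidirectional message paths.

    The elution proportion (fraction of the minor mobile-phase
    component) is broadcast onto every edge, giving edge-feature width 4.
    """
    if not 0.0 <= elution_proportion <= 1.0:
        raise ContractError(f"elution_proportion must be in [0, 1], got {elution_proportion}")
    mol = conformer.mol
    node_features = np.array([_atom_features(a) for a in mol.GetAtoms()], dtype=np.int64)
    node_features = node_features.reshape(mol.GetNumAtoms(), 9)
    src, dst, feats, bond_ids = [], [], [], []
    for b_idx, bond in enumerate(mol.GetBonds()):
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        bf = _bond_features(bond)
        for a, b in ((i, j), (j, i)):
            src.append(a)
            dst.append(b)
            feats.append(bf + [float(elution_proportion)])
            bond_ids.append(b_idx)
    edge_index = np.array([src, dst], dtype=np.int64).reshape(2, -1)
    edge_features = np.array(feats, dtype=np.float64).reshape(-1, 4)
    return GraphG(node_features, edge_index, edge_features, np.array(bond_ids, dtype=np.int64))


def build_bond_angle_graph(conformer: Conformer3D, descriptors: DescriptorVector) -> GraphH:
    """Build Graph H: bonds as nodes (feature = 3D length), bond-angle edges.

    An H edge joins every unordered pair of bonds sharing exactly one
    atom, in both directions; its feature is the angle at the shared
    atom followed by the five molecular descriptors.
    """
    mol = conformer.mol
    pos = conformer.atom_positions
    n_bonds = mol.GetNumBonds()
    if n_bonds == 0:
        raise FeaturizationError(
            f"molecule {conformer.smiles!r} has no bonds; Graph H undefined"
        )
    bond_atoms = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()]
    lengths = np.array(
        [np.linalg.norm(pos[i] - pos[j]) for i, j in bond_atoms]
    ).reshape(-1, 1)

    desc = descriptors.as_array()
    src, dst, feats = [], [], []
    # enumerate bond pairs sharing an atom via per-atom incidence lists
    incident: list[list[int]] = [[] for _ in range(mol.GetNumAtoms())]
    for b_idx, (i, j) in enumerate(bond_atoms):
        incident[i].append(b_idx)
        incident[j].append(b_idx)
    for atom_idx, bonds_here in enumerate(incident):
        for x in range(len(bonds_here)):
            for y in range(x + 1, len(bonds_here)):
                b1, b2 = bonds_here[x], bonds_here[y]
                angle = _bond_angle(pos, bond_atoms[b1], bond_atoms[b2], atom_idx)
                for a, b in ((b1, b2), (b2, b1)):
                    src.append(a)
                    dst.append(b)
                    feats.append(np.concatenate([[angle], desc]))
    edge_index = np.array([src, dst], dtype=np.int64).reshape(2, -1)
    edge_features = (
        np.array(feats, dtype=np.float64).reshape(-1, 6)
        if feats
        else np.empty((0, 6))
    )
    return GraphH(lengths, edge_index, edge_features)


def _bond_angle(pos, bond1, bond2, shared: int) -> float:
    """Angle in [0, π] between two bonds at their shared atom."""
    other1 = bond1[0] if bond1[1] == shared else bond1[1]
    other2 = bond2[0] if bond2[1] == shared else bond2[1]
    v1 = pos[other1] - pos[shared]
    v2 = pos[other2] - pos[shared]
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.arccos(np.clip(cosang, -1.0, 1.0)))


# -- molecular descriptors -------------------------------------------------


def compute_descriptors(smiles: str) -> DescriptorVector:
    """Compute the five 2D descriptors used as Graph H edge features."""
    mol = _parse_smiles(smiles)
    try:
        tpsa = float(Descriptors.TPSA(mol))
        total_asa = float(rdMolDescriptors.CalcLabuteASA(mol))
        contribs, _h_contrib = rdMolDescriptors._CalcLabuteASAContribs(mol)
        hydrophobic = polar = 0.0
        for c, atom in zip(contribs, mol.GetAtoms()):
            if atom.GetAtomicNum() in HYDROPHOBIC_ELEMENTS:
                hydrophobic += c
            elif atom.GetAtomicNum() in POLAR_ELEMENTS:
                polar += c
        rpsa = float(np.clip(polar / total_asa, 0.0, 1.0)) if total_asa > 0 else 0.0
        rasa = float(np.clip(hydrophobic / total_asa, 0.0, 1.0)) if total_asa > 0 else 0.0
        medc = _distance_edge_cc(mol)
        mats = _moran_lag1_mass(mol)
    except (ValueError, RuntimeError) as exc:  # pragma: no cover - rdkit internals
        raise FeaturizationError(f"descriptor computation failed for {smiles!r}: {exc}")
    vec = DescriptorVector(tpsa, rpsa, rasa, medc, mats)
    if not np.all(np.isfinite(vec.as_array())):
        raise FeaturizationError(f"non-finite descriptor for {smiles!r}: {vec}")
    return vec


def _distance_edge_cc(mol: Chem.Mol) -> float:
    """Distance-edge statistic over carbon pairs: n / (geometric mean d)²."""
    carbons = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() == 6]
    if len(carbons) < 2:
        return 0.0
    dmat = Chem.GetDistanceMatrix(mol)
    logs = [
        np.log(dmat[i][j])
        for k, i in enumerate(carbons)
        for j in carbons[k + 1 :]
    ]
    n = len(logs)
    gmean = np.exp(np.mean(logs))
    return float(n / gmean**2)


def _moran_lag1_mass(mol: Chem.Mol) -> float:
    """Moran autocorrelation of atomic mass over bonded atom pairs."""
    w = np.array([a.GetMass() for a in mol.GetAtoms()])
    n = len(w)
    dev = w - w.mean()
    denom = float(np.sum(dev**2))
    if denom == 0.0 or mol.GetNumBonds() == 0:
        return 0.0
    num = 0.0
    npairs = 0
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        num += 2 * dev[i] * dev[j]  # both ordered pairs
        npairs += 2
    return float((n / npairs) * (num / denom))


# -- column registry and augmentation --------------------------------------


def load_column_registry(path=None) -> dict[str, ColumnSpec]:
    """Load the column registry (name → ColumnSpec) from YAML.

    Without ``path`` the registry shipped with the package is used.  The
    shipped CSP descriptor vectors were computed with
    :func:`compute_descriptors` on the CSP monomer-unit structures and
    are editable configuration, not measured truth.
    """
    if path is None:
        ref = importlib.resources.files("chirsep") / "data" / "columns.yaml"
        raw = yaml.safe_load(ref.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    registry = {}
    for name, entry in raw["columns"].items():
        registry[name] = ColumnSpec(
            name=name,
            substrate_code=int(entry["substrate_code"]),
            connection_code=int(entry["connection_code"]),
            packing_size=float(entry["packing_size"]),
            csp_descriptors=np.asarray(entry["csp_descriptors"], float),
        )
    return registry


def augment_with_column(dual: DualGraph, column: ColumnSpec) -> DualGraph:
    """Append column information for multi-column models.

    G edges gain [packing_size, substrate_code, connection_code]
    (width 4 → 7); H edges gain the 5 CSP descriptors (width 6 → 11).
    """
    if dual.g.edge_features.shape[1] != 4 or dual.h.edge_features.shape[1] != 6:
        raise StateError("dual graph is already column-augmented")
    n_g = dual.g.edge_features.shape[0]
    n_h = dual.h.edge_features.shape[0]
    col_g = np.tile(
        [column.packing_size, float(column.substrate_code), float(column.connection_code)],
        (n_g, 1),
    )
    col_h = np.tile(column.csp_descriptors, (n_h, 1))
    g = replace(
        dual.g,
        edge_features=np.hstack([dual.g.edge_features, col_g]),
    )
    h = replace(
        dual.h,
        edge_features=(
            np.hstack([dual.h.edge_features, col_h]) if n_h else np.empty((0, 11))
        ),
    )
    return DualGraph(g, h, dual.smiles, dual.condition, column, dual.descriptors)


def build_dual_graph(
    smiles: str,
    condition: Condition,
    seed: int = 0,
    explicit_hs: bool = False,
    column: Optional[ColumnSpec] = None,
    descriptors: Optional[DescriptorVector] = None,
    conformer: Optional[Conformer3D] = None,
) -> DualGraph:
    """Featurize one molecule under one condition into a DualGraph.

    Passing ``conformer``/``descriptors`` lets callers cache the
    expensive per-molecule work across conditions.
    """
    if conformer is None:
        conformer = embed_conformer(smiles, seed=seed, explicit_hs=explicit_hs)
    if descriptors is None:
        descriptors = compute_descriptors(smiles)
    g = build_atom_bond_graph(conformer, condition.elution_proportion)
    h = build_bond_angle_graph(conformer, descriptors)
    dual = DualGraph(g, h, conformer.smiles, condition, None, descriptors)
    if column is not None:
        dual = augment_with_column(dual, column)
    return dual
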