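"""SMILES → bidirectional molecular graphs with numeric atom/bond features.

Molecules are hydrogen-suppressed heavy-atom graphs; every undirected bond
is stored as two directed edges so that message passing can treat each
direction independently.  Featurization schemes are self-contained and
deterministic; the default ``"minimal"`` scheme one-hot encodes atomic
number (over a fixed alphabet with an "other" slot) together with heavy
degree for atoms, and bond type for edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.error")

# fixed atom alphabet: common organic elements; anything else → "other"
ATOM_ALPHABET = ("C", "N", "O", "F", "P", "S", "Cl", "Br", "I")
MAX_DEGREE = 5
BOND_TYPES = (
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE,
    Chem.BondType.AROMATIC,
)

FEATURE_SCHEMES = ("minimal",)


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""

    def __init__(self, smiles: str, drug_id: str):
        self.smiles = smiles
        self.drug_id = drug_id
        super().__init__(f"unparsable SMILES for drug {drug_id!r}: {smiles!r}")


@dataclass
class MolecularGraph:
    """Bidirectional heavy-atom graph of one molecule.

    ``directed_edges`` lists each undirected bond twice, once per
    direction; feature matrices are row-aligned with atoms and directed
    edges respectively.
    """

    drug_id: str
    atom_count: int
    directed_edges: list[tuple[int, int]]
    node_features: np.ndarray | None = None
    edge_features: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def validate(self) -> None:
        for u, v in self.directed_edges:
            if not (0 <= u < self.atom_count and 0 <= v < self.atom_count):
                raise ValueError(f"edge ({u},{v}) out of range for {self.atom_count} atoms")
            if (v, u) not in set(self.directed_edges):
                raise ValueError(f"edge ({u},{v}) lacks its reverse — graph not bidirectional")
        if self.node_features is not None and self.node_features.shape[0] != self.atom_count:
            raise ValueError("node_features row count != atom_count")
        if self.edge_features is not None and self.edge_features.shape[0] != len(self.directed_edges):
            raise ValueError("edge_features row count != number of directed edges")


def parse_smiles(smiles: str, drug_id: str = "") -> MolecularGraph:
    """Parse one SMILES string into a :class:`MolecularGraph`.

    Hydrogens are suppressed; for multi-fragment inputs (salts) the
    largest fragment by heavy-atom count is kept.  Deterministic: the
    same SMILES always yields an identical graph.

    Raises
    ------
    SmilesParseError
        If RDKit cannot parse the string.
    """
    if not smiles:
        raise SmilesParseError(smiles, drug_id)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles, drug_id)
    frags = Chem.GetMolFrags(mol, asMols=True)
    if len(frags) > 1:
        mol = max(frags, key=lambda m: m.GetNumAtoms())

    edges: list[tuple[int, int]] = []
    for bond in mol.GetBonds():
        u, v = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        edges.append((u, v))
        edges.append((v, u))
    graph = MolecularGraph(drug_id=drug_id, atom_count=mol.GetNumAtoms(), directed_edges=edges)
    graph.metadata["mol"] = mol
    return graph


def _minimal_node_features(mol: Chem.Mol) -> np.ndarray:
    n_elem = len(ATOM_ALPHABET) + 1  # + "other"
    n_deg = MAX_DEGREE + 1
    feats = np.zeros((mol.GetNumAtoms(), n_elem + n_deg))
    for atom in mol.GetAtoms():
        i = atom.GetIdx()
        sym = atom.GetSymbol()
        slot = ATOM_ALPHABET.index(sym) if sym in ATOM_ALPHABET else n_elem - 1
        feats[i, slot] = 1.0
        feats[i, n_elem + min(atom.GetDegree(), MAX_DEGREE)] = 1.0
    return feats


def _minimal_edge_features(mol: Chem.Mol, directed_edges) -> np.ndarray:
    feats = np.zeros((len(directed_edges), len(BOND_TYPES)))
    for row, (u, v) in enumerate(directed_edges):
        bond = mol.GetBondBetweenAtoms(int(u), int(v))
        btype = bond.GetBondType()
        if btype in BOND_TYPES:
            feats[row, BOND_TYPES.index(btype)] = 1.0
    return feats


def featurize(graph: MolecularGraph, scheme: str = "minimal") -> MolecularGraph:
    """Populate node/edge feature matrices in place per the named scheme."""
    if scheme not in FEATURE_SCHEMES:
        raise ValueError(f"unknown featurization scheme {scheme!r}; known: {FEATURE_SCHEMES}")
    mol = graph.metadata.get("mol")
    if mol is None:
        raise ValueError("graph was not produced by parse_smiles (no molecule attached)")
    graph.node_features = _minimal_node_features(mol)
    graph.edge_features = _minimal_edge_features(mol, graph.directed_edges)
    graph.metadata["scheme"] = scheme
    graph.metadata["node_feature_dim"] = graph.node_features.shape[1]
    graph.metadata["edge_feature_dim"] = graph.edge_features.shape[1]
    return graph


def graphs_from_table(smiles_table: dict[str, str], scheme: str = "minimal",
                      on_error: str = "skip") -> dict[str, MolecularGraph]:
    """Parse + featurize a drug_id → SMILES table.

    ``on_error``: ``"skip"`` drops unparsable entries with a warning,
    ``"abort"`` re-raises.
    """
    if on_error not in ("skip", "abort"):
        raise ValueError("on_error must be 'skip' or 'abort'")
    graphs: dict[str, MolecularGraph] = {}
    for drug_id, smiles in smiles_table.items():
        try:
            graphs[drug_id] = featurize(parse_smiles(smiles, drug_id), scheme)
        except SmilesParseError:
            if on_error == "abort":
                raise
            logger.warning("skipping drug %s: unparsable SMILES %r", drug_id, smiles)
    return graphs
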