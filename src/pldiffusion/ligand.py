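"""Ligand SMILES parsing and categorical atom/bond featurization.

Atoms carry nine fields (atomic number, chirality, degree, formal charge,
attached hydrogens, radical electrons, hybridization, aromaticity, ring
membership); bonds carry three (bond type, stereochemistry, conjugation).
Each categorical field has a fixed vocabulary plus a final out-of-vocabulary
bucket.  The special SMILES ``"*"`` denotes a masked/unspecified ligand and
yields an empty graph flagged ``is_masked_ligand``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")  # rdkit parse chatter is surfaced as exceptions

__all__ = [
    "AtomRecord",
    "BondRecord",
    "LigandGraph",
    "featurize_ligand",
    "ATOM_VOCABS",
    "BOND_VOCABS",
    "SmilesParseError",
]

MASKED_LIGAND_SMILES = "*"

# Fixed categorical vocabularies; the last index of every field is the OOV
# bucket, applied when a value falls outside the listed range.
ATOM_VOCABS: dict[str, list] = {
    "atomic_number": list(range(1, 54)),  # H..I
    "chirality": ["CHI_UNSPECIFIED", "CHI_TETRAHEDRAL_CW", "CHI_TETRAHEDRAL_CCW", "CHI_OTHER"],
    "degree": list(range(0, 7)),
    "formal_charge": list(range(-3, 4)),
    "attached_hydrogens": list(range(0, 5)),
    "radical_electrons": list(range(0, 3)),
    "hybridization": ["S", "SP", "SP2", "SP3", "SP3D", "SP3D2"],
    "is_aromatic": [False, True],
    "in_ring": [False, True],
}

BOND_VOCABS: dict[str, list] = {
    "bond_type": ["SINGLE", "DOUBLE", "TRIPLE", "AROMATIC"],
    "stereochemistry": ["STEREONONE", "STEREOZ", "STEREOE", "STEREOCIS", "STEREOTRANS", "STEREOANY"],
    "is_conjugated": [False, True],
}


def vocab_size(vocab: list) -> int:
    return len(vocab) + 1  # trailing OOV bucket


def vocab_index(vocab: list, value) -> int:
    try:
        return vocab.index(value)
    except ValueError:
        return len(vocab)


class SmilesParseError(ValueError):
    pass


@dataclass(frozen=True)
class AtomRecord:
    atomic_number: int
    chirality: str
    degree: int
    formal_charge: int
    attached_hydrogens: int
    radical_electrons: int
    hybridization: str
    is_aromatic: bool
    in_ring: bool

    def field_indices(self) -> dict[str, int]:
        """Per-field vocabulary index (OOV-bucketed)."""
        return {
            name: vocab_index(vocab, getattr(self, name))
            for name, vocab in ATOM_VOCABS.items()
        }


@dataclass(frozen=True)
class BondRecord:
    atom_i: int
    atom_j: int
    bond_type: str
    stereochemistry: str
    is_conjugated: bool

    def field_indices(self) -> dict[str, int]:
        return {
            name: vocab_index(vocab, getattr(self, name))
            for name, vocab in BOND_VOCABS.items()
        }


@dataclass(frozen=True)
class LigandGraph:
    atoms: tuple[AtomRecord, ...]
    bonds: tuple[BondRecord, ...]
    is_masked_ligand: bool = False
    elements: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        n = len(self.atoms)
        for b in self.bonds:
            if not (0 <= b.atom_i < b.atom_j < n):
                raise ValueError(f"bond ({b.atom_i},{b.atom_j}) invalid for {n} atoms (need i < j)")
        if self.is_masked_ligand and n != 0:
            raise ValueError("a masked ligand must have zero atoms")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)


def featurize_ligand(smiles: str) -> LigandGraph:
    """Parse a SMILES string into a categorical feature graph.

    ``"*"`` produces the zero-atom masked-ligand graph.  One record per heavy
    atom; undirected bonds stored once with ``i < j``.
    """
    if smiles.strip() == MASKED_LIGAND_SMILES:
        return LigandGraph(atoms=(), bonds=(), is_masked_ligand=True)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparseable SMILES: {smiles!r}")
    atoms = tuple(
        AtomRecord(
            atomic_number=a.GetAtomicNum(),
            chirality=str(a.GetChiralTag()),
            degree=a.GetDegree(),
            formal_charge=a.GetFormalCharge(),
            attached_hydrogens=a.GetTotalNumHs(),
            radical_electrons=a.GetNumRadicalElectrons(),
            hybridization=str(a.GetHybridization()),
            is_aromatic=a.GetIsAromatic(),
            in_ring=a.IsInRing(),
        )
        for a in mol.GetAtoms()
    )
    bonds = tuple(
        BondRecord(
            atom_i=min(b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
            atom_j=max(b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
            bond_type=str(b.GetBondType()),
            stereochemistry=str(b.GetStereo()),
            is_conjugated=b.GetIsConjugated(),
        )
        for b in mol.GetBonds()
    )
    elements = tuple(a.GetSymbol() for a in mol.GetAtoms())
    return LigandGraph(atoms=atoms, bonds=bonds, is_masked_ligand=False, elements=elements)
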