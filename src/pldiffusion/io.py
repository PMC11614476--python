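"""PDB reading/writing for Calpha-trace + ligand complexes.

The on-disk convention: one ATOM record per residue (atom name CA, chain A),
one HETATM record per ligand heavy atom (residue LIG, chain L), occupancy
1.00, ``%8.3f`` coordinates, TER after the protein chain, END last.  Files
are read back with biotite (first altloc kept); residue numbering is
1-based in files and 0-based in memory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from biotite.structure.io.pdb import PDBFile

logger = logging.getLogger(__name__)

__all__ = ["StructureCoords", "read_structure", "write_pdb"]

_AA_1TO3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
    "X": "UNK", "#": "UNK",
}
_COORD_LIMIT = 9999.999  # %8.3f field capacity


@dataclass
class StructureCoords:
    """Labeled coordinates read from a PDB file (Angstrom)."""

    ca_coords: np.ndarray  # (n_res, 3)
    ligand_coords: np.ndarray  # (n_atoms, 3)
    residue_ids: np.ndarray  # 1-based ids as stored in the file

    @property
    def all_coords(self) -> np.ndarray:
        return np.concatenate([self.ca_coords, self.ligand_coords], axis=0)


def read_structure(path, skip_missing_ca: bool = False) -> StructureCoords:
    """Read Calpha trace + ligand heavy atoms from a PDB file.

    The first altloc is kept.  A residue without a CA atom raises unless
    ``skip_missing_ca`` is set, in which case it is skipped with a warning.
    """
    pdb = PDBFile.read(str(path))
    try:
        arr = pdb.get_structure(model=1, altloc="first")
    except Exception as exc:
        raise ValueError(f"empty structure: no ATOM/HETATM records in {path}") from exc
    if arr.array_length() == 0:
        raise ValueError(f"empty structure: no ATOM/HETATM records in {path}")
    protein = arr[~arr.hetero]
    ligand = arr[arr.hetero]
    ca_list, res_ids = [], []
    if protein.array_length():
        for res_id in np.unique(protein.res_id):
            res_atoms = protein[protein.res_id == res_id]
            ca = res_atoms[res_atoms.atom_name == "CA"]
            if ca.array_length() == 0:
                msg = f"residue {int(res_id)} in {path} has no CA atom"
                if skip_missing_ca:
                    logger.warning("%s; skipped", msg)
                    continue
                raise ValueError(msg)
            ca_list.append(ca.coord[0])
            res_ids.append(int(res_id))
    return StructureCoords(
        ca_coords=np.array(ca_list).reshape(-1, 3),
        ligand_coords=np.asarray(ligand.coord, dtype=np.float64).reshape(-1, 3),
        residue_ids=np.array(res_ids, dtype=np.int64),
    )


def write_pdb(complex_, path) -> None:
    """Write a complex (ToyComplex or equivalent) in the package convention."""
    coords = np.asarray(complex_.coords, dtype=np.float64)
    if np.abs(coords).max() > _COORD_LIMIT:
        raise ValueError("coordinates overflow the fixed-width PDB field")
    n_res = len(complex_.sequence)
    lines = []
    serial = 0
    for i, token in enumerate(complex_.sequence.residues):
        serial += 1
        x, y, z = coords[i]
        res3 = _AA_1TO3.get(token, "UNK")
        lines.append(
            f"ATOM  {serial:5d}  CA  {res3:>3s} A{i + 1:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append(f"TER   {serial + 1:5d}      {_AA_1TO3.get(complex_.sequence.residues[-1], 'UNK'):>3s} A{n_res:4d}")
    serial += 1
    elements = getattr(complex_.ligand, "elements", ()) or ()
    counts: dict[str, int] = {}
    for k in range(complex_.ligand.n_atoms):
        serial += 1
        x, y, z = coords[n_res + k]
        elem = elements[k] if k < len(elements) else "C"
        counts[elem] = counts.get(elem, 0) + 1
        name = f"{elem}{counts[elem]}"
        lines.append(
            f"HETATM{serial:5d} {name:<4s} LIG L{1:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {elem:>2s}"
        )
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
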