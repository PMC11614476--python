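"""Deterministic toy protein-ligand complexes and a stub residue embedder.

The generator emulates the shape of real training examples — a random
sequence over the 20 canonical amino acids, a chain-like self-avoiding
Calpha trace with ~3.8 A steps, and ligand heavy atoms placed in a shell
around a surface residue — without any claim to physical realism (no
secondary structure, rotamers or binding chemistry).  Everything is
reproducible from (n_res, smiles, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np

from .diffusion import center
from .ligand import LigandGraph, featurize_ligand
from .sequence import CANONICAL_AA, AminoAcidSequence

__all__ = ["ToyComplex", "generate_toy_complex", "StubEmbedder", "make_fixture_suite"]

STEP_LENGTH = 3.8  # Angstrom, consecutive Calpha spacing
STEP_JITTER = 0.3
MIN_NONCONSECUTIVE = 2.5  # self-avoidance cutoff
LIGAND_SHELL = 4.0  # ligand atoms stay within this radius of the anchor

#: small ligand menu covering rings, aromaticity, conjugation and masking
LIGAND_MENU = ("CCO", "c1ccccc1", "CC(=O)O", "*")


@dataclass(frozen=True)
class ToyComplex:
    sequence: AminoAcidSequence
    ligand_smiles: str
    ligand: LigandGraph
    coords: np.ndarray  # (n_res + n_atoms, 3), zero centroid
    seed: int

    @property
    def n_tokens(self) -> int:
        return len(self.sequence) + self.ligand.n_atoms

    @property
    def protein_coords(self) -> np.ndarray:
        return self.coords[: len(self.sequence)]

    @property
    def ligand_coords(self) -> np.ndarray:
        return self.coords[len(self.sequence) :]


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def _build_chain(n_res: int, rng: np.random.Generator) -> np.ndarray:
    """Self-avoiding random walk with ~3.8 A steps, 2.5 A exclusion."""
    for _attempt in range(50):
        pts = [np.zeros(3)]
        failed = False
        for _i in range(1, n_res):
            placed = False
            for _try in range(200):
                step = STEP_LENGTH + rng.uniform(-STEP_JITTER, STEP_JITTER)
                cand = pts[-1] + step * _random_unit(rng)
                prior = np.array(pts[:-1]) if len(pts) > 1 else None
                if prior is None or np.linalg.norm(prior - cand, axis=1).min() >= MIN_NONCONSECUTIVE:
                    pts.append(cand)
                    placed = True
                    break
            if not placed:
                failed = True
                break
        if not failed:
            return np.array(pts)
    raise RuntimeError(f"chain placement failed for n_res={n_res}")


def _place_ligand(
    chain: np.ndarray, n_atoms: int, rng: np.random.Generator
) -> np.ndarray:
    """Atoms in a shell around a randomly chosen surface residue."""
    if n_atoms == 0:
        return np.zeros((0, 3))
    centroid = chain.mean(0)
    dist = np.linalg.norm(chain - centroid, axis=1)
    surface = np.argsort(dist)[-max(1, len(chain) // 3):]
    anchor = chain[rng.choice(surface)]
    atoms: list[np.ndarray] = []
    for _ in range(n_atoms):
        for _try in range(500):
            cand = anchor + rng.uniform(1.5, LIGAND_SHELL) * _random_unit(rng)
            ok_lig = not atoms or np.linalg.norm(np.array(atoms) - cand, axis=1).min() >= 1.0
            ok_chain = np.linalg.norm(chain - cand, axis=1).min() >= 1.5
            if ok_lig and ok_chain:
                atoms.append(cand)
                break
        else:
            raise RuntimeError("ligand placement failed after bounded retries")
    return np.array(atoms)


def generate_toy_complex(n_res: int, ligand_smiles: str, seed: int) -> ToyComplex:
    """Deterministic toy complex: random sequence + chain trace + ligand shell."""
    if not 4 <= n_res <= 200:
        raise ValueError(f"n_res must be in [4, 200], got {n_res}")
    ligand = featurize_ligand(ligand_smiles)
    rng = np.random.default_rng(seed)
    sequence = AminoAcidSequence(
        tuple(rng.choice(list(CANONICAL_AA), size=n_res))
    )
    chain = _build_chain(n_res, rng)
    lig_coords = _place_ligand(chain, ligand.n_atoms, rng)
    coords = center(np.concatenate([chain, lig_coords], axis=0))
    return ToyComplex(
        sequence=sequence, ligand_smiles=ligand_smiles, ligand=ligand,
        coords=coords, seed=seed,
    )


class StubEmbedder:
    """Deterministic per-residue embedding keyed by (token, position, seed).

    Each residue's vector is a standard-normal draw from a generator seeded
    by a stable hash of the token identity, its position and the embedder
    seed, so identical tokens at identical positions map identically across
    calls and across processes.
    """

    def __init__(self, dim: int, seed: int = 0):
        if dim < 1:
            raise ValueError("dim must be >= 1")
        self.dim = dim
        self.seed = seed

    def _vector(self, token: str, position: int) -> np.ndarray:
        key = f"{token}|{position}|{self.seed}".encode()
        h = int.from_bytes(hashlib.sha256(key).digest()[:4], "little")
        return np.random.default_rng(h).standard_normal(self.dim)

    def __call__(self, sequence: AminoAcidSequence) -> np.ndarray:
        return np.stack(
            [self._vector(tok, i) for i, tok in enumerate(sequence.residues)]
        )


def make_fixture_suite(out_dir, n: int, seed: int, n_res: int = 16) -> dict:
    """Write n toy complexes as PDB + FASTA (+ one SMILES list) and a manifest."""
    from pathlib import Path

    from .io import write_pdb
    from .sequence import write_fasta

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    smiles_lines = []
    for i in range(n):
        fixture_seed = seed + i
        smiles = LIGAND_MENU[i % len(LIGAND_MENU)]
        complex_ = generate_toy_complex(n_res, smiles, fixture_seed)
        pdb_path = out / f"fixture_{i:03d}.pdb"
        fasta_path = out / f"fixture_{i:03d}.fasta"
        write_pdb(complex_, pdb_path)
        write_fasta(fasta_path, complex_.sequence, name=f"fixture_{i:03d}")
        smiles_lines.append(smiles)
        entries.append(
            {
                "index": i,
                "seed": fixture_seed,
                "n_res": n_res,
                "smiles": smiles,
                "pdb": pdb_path.name,
                "fasta": fasta_path.name,
                "pdb_sha256": hashlib.sha256(pdb_path.read_bytes()).hexdigest(),
                "fasta_sha256": hashlib.sha256(fasta_path.read_bytes()).hexdigest(),
            }
        )
    (out / "ligands.smi").write_text("\n".join(smiles_lines) + "\n")
    manifest = {"n": n, "seed": seed, "n_res": n_res, "fixtures": entries}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
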