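"""Amino-acid sequences, the masking scheme, and FASTA I/O.

The token alphabet has 22 symbols: the 20 canonical amino acids, an
``UNKNOWN`` token (``X``) for non-canonical residues, and a ``MASK`` token
(``#``) marking positions to be redesigned.

Masking is two-stage: an effective ratio is drawn uniformly from
``[0, mask_ratio]`` per call, then ``round(ratio * n)`` positions are chosen
uniformly without replacement.  The training signal therefore sees masking
levels varying continuously from zero up to the configured ceiling, and the
expected masked fraction is ``mask_ratio / 2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import SeqIO

__all__ = [
    "CANONICAL_AA",
    "UNKNOWN_TOKEN",
    "MASK_TOKEN",
    "ALPHABET",
    "TOKEN_INDEX",
    "AminoAcidSequence",
    "stochastic_mask",
    "read_fasta",
    "write_fasta",
]

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
UNKNOWN_TOKEN = "X"
MASK_TOKEN = "#"
ALPHABET = tuple(CANONICAL_AA) + (UNKNOWN_TOKEN, MASK_TOKEN)
TOKEN_INDEX = {t: i for i, t in enumerate(ALPHABET)}


@dataclass(frozen=True)
class AminoAcidSequence:
    """An ordered, validated list of residue tokens."""

    residues: tuple[str, ...]

    def __post_init__(self):
        if len(self.residues) < 1:
            raise ValueError("sequence must contain at least one residue")
        bad = [t for t in self.residues if t not in TOKEN_INDEX]
        if bad:
            raise ValueError(f"tokens outside the 22-symbol alphabet: {sorted(set(bad))}")

    @classmethod
    def from_string(cls, s: str) -> "AminoAcidSequence":
        return cls(tuple(s.upper()))

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return "".join(self.residues)

    def indices(self) -> np.ndarray:
        """Integer token ids in alphabet order."""
        return np.array([TOKEN_INDEX[t] for t in self.residues], dtype=np.int64)

    def masked_positions(self) -> np.ndarray:
        return np.array(
            [i for i, t in enumerate(self.residues) if t == MASK_TOKEN], dtype=np.int64
        )


def stochastic_mask(
    sequence: AminoAcidSequence, mask_ratio: float, seed: int
) -> AminoAcidSequence:
    """Replace a random subset of residues by MASK.

    The effective ratio is drawn ~ Uniform(0, mask_ratio), then
    ``round(effective * n)`` distinct positions are masked.  ``mask_ratio=0``
    is the identity.
    """
    if not 0.0 <= mask_ratio <= 1.0:
        raise ValueError(f"mask_ratio must lie in [0, 1], got {mask_ratio}")
    if mask_ratio == 0.0:
        return sequence
    rng = np.random.default_rng(seed)
    n = len(sequence)
    effective = rng.uniform(0.0, mask_ratio)
    k = int(round(effective * n))
    positions = rng.choice(n, size=k, replace=False)
    residues = list(sequence.residues)
    for p in positions:
        residues[p] = MASK_TOKEN
    return AminoAcidSequence(tuple(residues))


def read_fasta(path, index: int = 0) -> AminoAcidSequence:
    """Read one record from a FASTA file (first record by default)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if index >= len(records):
        raise IndexError(f"record {index} requested but file has {len(records)}")
    return AminoAcidSequence.from_string(str(records[index].seq))


def write_fasta(path, sequence: AminoAcidSequence, name: str = "designed") -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        s = str(sequence)
        for i in range(0, len(s), 60):
            fh.write(s[i : i + 60] + "\n")
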