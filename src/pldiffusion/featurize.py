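"""Initial single and pair representations for a protein-ligand complex.

Token ordering is residues-then-ligand-atoms everywhere.  Residue rows of the
single representation combine a learned token embedding with a normalized,
linearly mapped per-residue embedding from a pluggable embedder (the hook a
protein language model plugs into); ligand-atom rows sum the per-field
categorical feature embeddings.  The pair representation accumulates

* clipped relative-position encodings on residue-residue entries,
* symmetric bond-feature embeddings on bonded ligand-atom entries,
* Gaussian radial-basis embeddings of current inter-token distances
  (zeros when no coordinates are supplied), and
* a broadcast sinusoidal embedding of diffusion time.

Distance features depend on coordinates only through pairwise distances, so
the whole featurization is invariant under rigid motions — the property the
downstream denoiser's SE(3) equivariance rests on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol

import numpy as np

from ._tensor import Tensor
from .config import RunConfig
from .ligand import ATOM_VOCABS, BOND_VOCABS, LigandGraph, vocab_size
from .nn import Embedding, LayerNorm, Linear, Module
from .sequence import AminoAcidSequence

__all__ = [
    "Embedder",
    "SingleRepresentation",
    "PairRepresentation",
    "ComplexFeaturizer",
    "rbf_embedding",
    "time_embedding",
    "relative_position_onehot",
    "RESIDUE_KIND",
    "LIGAND_KIND",
]

RESIDUE_KIND = 0
LIGAND_KIND = 1


class Embedder(Protocol):
    """Per-residue embedding source (e.g. a protein language model)."""

    dim: int

    def __call__(self, sequence: AminoAcidSequence) -> np.ndarray:
        """Return an array of shape (len(sequence), dim)."""
        ...


@dataclass
class SingleRepresentation:
    values: Tensor  # (1, r, c_m)
    token_kinds: np.ndarray  # (r,) RESIDUE_KIND / LIGAND_KIND
    n_res: int
    n_atoms: int

    @property
    def n_tokens(self) -> int:
        return self.n_res + self.n_atoms


@dataclass
class PairRepresentation:
    values: Tensor  # (1, r, r, c_z)


def rbf_embedding(distances: np.ndarray, centers: np.ndarray, width: float) -> np.ndarray:
    """Gaussian radial basis: exp(-(d - mu_k)^2 / (2 w^2)); 1 at the center."""
    d = distances[..., None]
    return np.exp(-0.5 * ((d - centers) / width) ** 2)


def time_embedding(t: float, dim: int) -> np.ndarray:
    """Sinusoidal embedding of diffusion time; sin half then cos half.

    Frequencies are a geometric ladder pi * 2^k so that t in [0, 1] is
    resolved at several scales; at t=0 all sines are 0 and all cosines 1.
    """
    half = dim // 2
    freqs = np.pi * 2.0 ** np.arange(half)
    return np.concatenate([np.sin(freqs * t), np.cos(freqs * t)])


def relative_position_onehot(n_res: int, r_max: int) -> np.ndarray:
    """(n_res, n_res, 2*r_max+1) one-hot of clip(j - i, -r_max, r_max)."""
    idx = np.arange(n_res)
    offset = np.clip(idx[None, :] - idx[:, None], -r_max, r_max) + r_max
    eye = np.eye(2 * r_max + 1)
    return eye[offset]


class ComplexFeaturizer(Module):
    """Learned featurization producing the initial (single, pair) tensors."""

    def __init__(self, cfg: RunConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.token_embedding = Embedding(22, cfg.c_m, rng)
        self.embedder_norm = LayerNorm(cfg.embedder_dim)
        self.embedder_map = Linear(cfg.embedder_dim, cfg.c_m, rng)
        self.atom_field_names = list(ATOM_VOCABS)
        self.atom_field_embeddings = [
            Embedding(vocab_size(ATOM_VOCABS[name]), cfg.c_m, rng)
            for name in self.atom_field_names
        ]
        self.bond_field_names = list(BOND_VOCABS)
        self.bond_field_embeddings = [
            Embedding(vocab_size(BOND_VOCABS[name]), cfg.c_z, rng)
            for name in self.bond_field_names
        ]
        self.relpos_linear = Linear(2 * cfg.r_max + 1, cfg.c_z, rng, bias=False)
        self.rbf_linear = Linear(cfg.n_rbf, cfg.c_z, rng, bias=False)
        self.time_linear = Linear(cfg.time_dim, cfg.c_z, rng, bias=False)
        centers = np.linspace(cfg.rbf_min, cfg.rbf_max, cfg.n_rbf)
        self._rbf_centers = centers
        self._rbf_width = float(centers[1] - centers[0]) if cfg.n_rbf > 1 else 1.0

    # ------------------------------------------------------------- single
    def build_single(
        self,
        masked_seq: AminoAcidSequence,
        ligand: LigandGraph,
        embedder: Embedder,
    ) -> SingleRepresentation:
        n_res, n_atoms = len(masked_seq), ligand.n_atoms
        emb = np.asarray(embedder(masked_seq), dtype=np.float64)
        if emb.shape != (n_res, self.cfg.embedder_dim):
            raise ValueError(
                f"embedder returned {emb.shape}, expected ({n_res}, {self.cfg.embedder_dim})"
            )
        residue_rows = self.token_embedding(masked_seq.indices()) + self.embedder_map(
            self.embedder_norm(Tensor(emb))
        )
        rows = [residue_rows]
        if n_atoms:
            idx = {
                name: np.array([a.field_indices()[name] for a in ligand.atoms])
                for name in self.atom_field_names
            }
            atom_rows = self.atom_field_embeddings[0](idx[self.atom_field_names[0]])
            for name, table in zip(self.atom_field_names[1:], self.atom_field_embeddings[1:]):
                atom_rows = atom_rows + table(idx[name])
            rows.append(atom_rows)
        from ._tensor import concat

        values = rows[0] if len(rows) == 1 else concat(rows, axis=0)
        values = values.reshape(1, n_res + n_atoms, self.cfg.c_m)
        kinds = np.concatenate(
            [np.full(n_res, RESIDUE_KIND), np.full(n_atoms, LIGAND_KIND)]
        ).astype(np.int64)
        return SingleRepresentation(values=values, token_kinds=kinds, n_res=n_res, n_atoms=n_atoms)

    # --------------------------------------------------------------- pair
    def build_pair(
        self,
        single: SingleRepresentation,
        ligand: LigandGraph,
        coords: np.ndarray | None,
        t: float,
    ) -> PairRepresentation:
        cfg = self.cfg
        r = single.n_tokens
        n_res = single.n_res
        if coords is not None:
            coords = np.asarray(coords, dtype=np.float64)
            if coords.shape != (r, 3):
                raise ValueError(f"coords shape {coords.shape} does not match {r} tokens")

        # relative positions (residue-residue block only)
        rel = relative_position_onehot(n_res, cfg.r_max)  # (n,n,2r+1)
        rel_feat = self.relpos_linear(Tensor(rel))  # (n,n,c_z) tensor
        # embed the residue-residue block into the full token grid
        full_rel = _embed_block(rel_feat, r, n_res, cfg.c_z)

        # bond features, symmetric on (i,j) and (j,i) ligand-atom entries
        bond_sum = None
        if ligand.bonds:
            bidx = {
                name: np.array([b.field_indices()[name] for b in ligand.bonds])
                for name in self.bond_field_names
            }
            bond_rows = self.bond_field_embeddings[0](bidx[self.bond_field_names[0]])
            for name, table in zip(self.bond_field_names[1:], self.bond_field_embeddings[1:]):
                bond_rows = bond_rows + table(bidx[name])  # (n_bonds, c_z)
            scatter = np.zeros((len(ligand.bonds), r, r))
            for k, b in enumerate(ligand.bonds):
                i, j = n_res + b.atom_i, n_res + b.atom_j
                scatter[k, i, j] = 1.0
                scatter[k, j, i] = 1.0
            from ._tensor import einsum

            bond_sum = einsum("kij,kc->ijc", Tensor(scatter), bond_rows)

        # distance RBF (all token pairs) when coordinates are available
        if coords is not None:
            diff = coords[:, None, :] - coords[None, :, :]
            dist = np.sqrt((diff**2).sum(-1))
            rbf = rbf_embedding(dist, self._rbf_centers, self._rbf_width)
        else:
            rbf = np.zeros((r, r, cfg.n_rbf))
        dist_feat = self.rbf_linear(Tensor(rbf))

        # broadcast time embedding
        te = time_embedding(t, cfg.time_dim)
        time_feat = self.time_linear(Tensor(np.broadcast_to(te, (r, r, cfg.time_dim)).copy()))

        pair = full_rel + dist_feat + time_feat
        if bond_sum is not None:
            pair = pair + bond_sum
        return PairRepresentation(values=pair.reshape(1, r, r, cfg.c_z))


def _embed_block(block: Tensor, r: int, n_res: int, c_z: int) -> Tensor:
    """Place an (n_res, n_res, c) tensor into the top-left of an (r, r, c) grid."""
    if n_res == r:
        return block
    from ._tensor import einsum

    sel = np.zeros((r, n_res))
    sel[:n_res, :] = np.eye(n_res)
    selt = Tensor(sel)
    return einsum("ia,jb,abc->ijc", selt, selt, block)
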