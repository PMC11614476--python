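"""SE(3)-equivariant noise prediction and the sequence logit head.

The final pair representation is symmetrized over the token axes and pushed
through a per-entry MLP to a scalar weight matrix W.  The noise prediction
for token i is the W-weighted sum of unit-normalized relative differences

    eps_i = sum_{j != i} W_ij (z_i - z_j) / (||z_i - z_j|| + delta)

followed by subtraction of the centroid over all tokens.  Because W depends
on coordinates only through rotation/translation-invariant distance
features, the map z -> eps is SE(3)-equivariant and the output lives in the
zero-centroid subspace.
"""

from __future__ import annotations

import numpy as np

from ._tensor import Tensor, einsum
from .config import RunConfig
from .featurize import PairRepresentation, SingleRepresentation
from .nn import Linear, MLP, Module

__all__ = ["PairToWeights", "predict_noise", "SequenceHead", "COINCIDENCE_DELTA"]

#: regularizer (in Angstrom) added to the pair-distance denominator so that
#: exactly coincident tokens contribute a vanishing, finite term
COINCIDENCE_DELTA = 1e-6


class PairToWeights(Module):
    """Symmetrize the pair tensor and map each entry to a scalar weight."""

    def __init__(self, cfg: RunConfig, rng: np.random.Generator):
        self.mlp = MLP([cfg.c_z, cfg.weight_mlp_hidden, 1], rng)

    def __call__(self, pair: PairRepresentation) -> Tensor:
        z = pair.values  # (b, r, r, c_z)
        z_sym = (z + z.transpose((0, 2, 1, 3))) * 0.5
        w = self.mlp(z_sym)  # (b, r, r, 1)
        b, r, _, _ = z.shape
        return w.reshape(b, r, r)


def predict_noise(weights: Tensor, coords: np.ndarray) -> Tensor:
    """Equivariant noise field from a weight matrix and current coordinates.

    ``coords`` is (r, 3); ``weights`` is (b, r, r).  Returns (b, r, 3) with
    zero centroid per batch element.
    """
    coords = np.asarray(coords, dtype=np.float64)
    r = coords.shape[0]
    if weights.shape[-1] != r:
        raise ValueError(f"weights for {weights.shape[-1]} tokens but {r} coordinates")
    diff = coords[:, None, :] - coords[None, :, :]  # (r, r, 3)
    norm = np.sqrt((diff**2).sum(-1)) + COINCIDENCE_DELTA
    unit = diff / norm[..., None]
    unit[np.arange(r), np.arange(r)] = 0.0  # exclude the j = i term
    field = einsum("bij,ijd->bid", weights, Tensor(unit))
    centered = field - field.mean(axis=1, keepdims=True)
    if not np.isfinite(centered.data).all():
        raise FloatingPointError("non-finite noise prediction")
    return centered


class SequenceHead(Module):
    """Linear map c_m -> 20 amino-acid logits on residue rows only."""

    def __init__(self, cfg: RunConfig, rng: np.random.Generator):
        self.proj = Linear(cfg.c_m, 20, rng)

    def __call__(self, single: SingleRepresentation) -> Tensor:
        # token ordering is residues-then-ligand-atoms, so residue rows are a prefix
        residue_rows = single.values[:, : single.n_res, :]
        return self.proj(residue_rows)  # (b, n_res, 20)
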