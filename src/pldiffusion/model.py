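"""The full noise-prediction model: featurizer -> trunk -> heads."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._tensor import Tensor
from .config import RunConfig
from .denoiser import PairToWeights, SequenceHead, predict_noise
from .featurize import ComplexFeaturizer, Embedder
from .ligand import LigandGraph
from .nn import Module, load_checkpoint, save_checkpoint
from .sequence import AminoAcidSequence
from .trunk import Trunk

__all__ = ["RedesignModel", "DenoiserOutput"]


@dataclass
class DenoiserOutput:
    eps_hat: Tensor  # (1, r, 3), zero centroid
    logits: Tensor  # (1, n_res, 20)
    weights: Tensor  # (1, r, r), symmetric


class RedesignModel(Module):
    """Joint sequence/structure denoiser for one protein-ligand complex.

    The featurizer is re-run on every call with the current noisy
    coordinates and diffusion time, so distance features always reflect the
    latent state being denoised.
    """

    def __init__(self, cfg: RunConfig, embedder: Embedder, seed: int | None = None):
        rng = np.random.default_rng(cfg.seed if seed is None else seed)
        self.cfg = cfg
        self.embedder = embedder
        self.featurizer = ComplexFeaturizer(cfg, rng)
        self.trunk = Trunk(cfg, rng)
        self.pair_to_weights = PairToWeights(cfg, rng)
        self.sequence_head = SequenceHead(cfg, rng)

    def __call__(
        self,
        masked_seq: AminoAcidSequence,
        ligand: LigandGraph,
        coords: np.ndarray | None,
        t: float,
    ) -> DenoiserOutput:
        single = self.featurizer.build_single(masked_seq, ligand, self.embedder)
        pair = self.featurizer.build_pair(single, ligand, coords, t)
        single, pair = self.trunk(single, pair)
        weights = self.pair_to_weights(pair)
        if coords is None:
            raise ValueError("noise prediction requires current coordinates")
        eps_hat = predict_noise(weights, coords)
        logits = self.sequence_head(single)
        return DenoiserOutput(eps_hat=eps_hat, logits=logits, weights=weights)

    # ---------------------------------------------------------- checkpoints
    def save(self, path) -> None:
        save_checkpoint(path, self, config=self.cfg.model_dump())

    @classmethod
    def restore(cls, path, embedder: Embedder) -> "RedesignModel":
        state, config = load_checkpoint(path)
        model = cls(RunConfig(**config), embedder)
        model.load_state_dict(state)
        return model
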