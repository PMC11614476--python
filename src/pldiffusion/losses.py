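"""The composite training objective L = L_WS + L_KL + L_CE and one SGD step.

* L_WS: per-sample Euclidean norm ||eps - eps_hat|| over all atom
  coordinates — a one-draw Monte-Carlo estimate of the sum over diffusion
  times, with t drawn uniformly per example per step.
* L_KL: schedule-weighted categorical KL between the model's predicted
  sequence distribution and the forward-process state of the true sequence,
  both pushed to time t - 1/T; the temporal weight is
  beta(t) = 1 - alpha(t)^2 / alpha(t - 1/T)^2 (the discrete-time noise
  increment, non-negative for a monotone schedule).
* L_CE: mean categorical cross-entropy over masked residue positions.

The sequence forward process mixes the one-hot distribution with the
uniform over the 20 canonical amino acids: q_t = alpha_t^2 p + (1 -
alpha_t^2)/20, so sequence information decays on the same clock as
coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._tensor import Tensor
from .diffusion import NoiseSchedule, center, sample_centered_noise
from .nn import Adam
from .sequence import AminoAcidSequence, stochastic_mask

logger = logging.getLogger(__name__)

__all__ = [
    "LossBreakdown",
    "ws_loss",
    "kl_sequence_loss",
    "ce_loss",
    "sequence_forward_probs",
    "beta_weight",
    "training_step",
]

_PROB_FLOOR = 1e-8
N_AA = 20
_warned_empty_ce = False


@dataclass(frozen=True)
class LossBreakdown:
    l_ws: float
    l_kl: float
    l_ce: float

    @property
    def total(self) -> float:
        return self.l_ws + self.l_kl + self.l_ce


def ws_loss(eps: np.ndarray | Tensor, eps_hat: Tensor) -> Tensor:
    """Euclidean norm of the noise-prediction residual, mean over batch."""
    eps_t = eps if isinstance(eps, Tensor) else Tensor(np.asarray(eps, dtype=np.float64))
    if eps_t.shape != eps_hat.shape:
        raise ValueError(f"shape mismatch: eps {eps_t.shape} vs eps_hat {eps_hat.shape}")
    d = eps_t - eps_hat
    if d.ndim == 2:  # (r, 3) single sample
        return ((d * d).sum() + 0.0) ** 0.5
    sq = (d * d).sum(axis=tuple(range(1, d.ndim)))  # per batch element
    return (sq**0.5).mean()


def sequence_forward_probs(probs: Tensor | np.ndarray, t: float, sched: NoiseSchedule):
    """Push a per-residue distribution through the sequence forward process."""
    a2 = float(sched.alpha(max(t, 0.0))) ** 2
    if isinstance(probs, Tensor):
        return probs * a2 + (1.0 - a2) / N_AA
    return np.asarray(probs) * a2 + (1.0 - a2) / N_AA


def beta_weight(sched: NoiseSchedule, t: float) -> float:
    """beta(t) = 1 - alpha(t)^2 / alpha(t - 1/T)^2 >= 0."""
    t_prev = max(t - 1.0 / sched.T, 0.0)
    return float(1.0 - (sched.alpha(t) / sched.alpha(t_prev)) ** 2)


def kl_sequence_loss(
    pred: Tensor, target: np.ndarray, weight: float = 1.0
) -> Tensor:
    """weight * mean_i KL(target_i || pred_i) over residues.

    ``pred`` rows must lie on the probability simplex (they are floored at
    1e-8 before the log to keep zero-support predictions finite; clipping is
    logged).  Zero-mass target entries contribute nothing.
    """
    target = np.asarray(target, dtype=np.float64)
    if target.shape != pred.shape:
        raise ValueError(f"shape mismatch: target {target.shape} vs pred {pred.shape}")
    if (pred.data < _PROB_FLOOR).any():
        logger.warning("kl_sequence_loss: prediction probabilities floored at %g", _PROB_FLOOR)
    pred_safe = pred.clip_min(_PROB_FLOOR)
    t_safe = np.where(target > 0, target, 1.0)
    const = float((target * np.log(t_safe)).sum(axis=-1).mean())
    cross = (Tensor(target) * pred_safe.log()).sum(axis=-1).mean()
    return (const - cross) * weight


def ce_loss(
    logits: Tensor, truth: AminoAcidSequence, positions: np.ndarray | None = None
) -> Tensor:
    """Mean cross-entropy of the true amino acid at the given positions.

    Defaults to the masked positions of ``truth``'s masked counterpart being
    unavailable here, callers pass the mask-position set explicitly; an
    empty set yields 0 with a warning.
    """
    if logits.ndim == 3:
        logits = logits.reshape(logits.shape[1], logits.shape[2])
    if positions is None:
        positions = np.arange(len(truth))
    positions = np.asarray(positions, dtype=np.int64)
    if positions.size == 0:
        # expected whenever the two-stage mask draw lands on zero positions
        global _warned_empty_ce
        if not _warned_empty_ce:
            logger.warning("ce_loss: empty position set, returning 0 "
                           "(further occurrences logged at DEBUG)")
            _warned_empty_ce = True
        else:
            logger.debug("ce_loss: empty position set, returning 0")
        return Tensor(0.0)
    classes = truth.indices()[positions]
    if (classes >= N_AA).any():
        raise ValueError("cross-entropy target contains non-canonical residues")
    logp = logits.log_softmax(axis=-1)
    picked = logp[positions, classes]
    return -picked.mean()


def training_step(
    model,
    batch: list,
    optimizer: Adam,
    sched: NoiseSchedule,
    seed: int,
    mask_ratio: float | None = None,
) -> LossBreakdown:
    """One seeded gradient update on a batch of reference complexes.

    For each example: draw t ~ U(0, 1], mask the sequence, forward-sample
    coordinates, run the model, accumulate the three losses; then apply one
    Adam update on the batch mean.  Fully reproducible given ``seed``.
    """
    rng = np.random.default_rng(seed)
    ratio = model.cfg.mask_ratio if mask_ratio is None else mask_ratio
    n = len(batch)
    l_ws_acc = Tensor(0.0)
    l_kl_acc = Tensor(0.0)
    l_ce_acc = Tensor(0.0)
    for example in batch:
        t = float(rng.uniform(1.0 / sched.T, 1.0))
        masked = stochastic_mask(example.sequence, ratio, seed=int(rng.integers(2**31)))
        x = center(example.coords)
        eps = sample_centered_noise(rng, x.shape[0])
        z_t = float(sched.alpha(t)) * x + float(sched.sigma(t)) * eps
        out = model(masked, example.ligand, z_t, t)

        l_ws = ws_loss(eps, out.eps_hat.reshape(*eps.shape))

        probs = out.logits.reshape(len(example.sequence), N_AA).softmax(axis=-1)
        t_prev = t - 1.0 / sched.T
        pred_prev = sequence_forward_probs(probs, t_prev, sched)
        onehot = np.eye(N_AA)[np.minimum(example.sequence.indices(), N_AA - 1)]
        target_prev = sequence_forward_probs(onehot, t_prev, sched)
        l_kl = kl_sequence_loss(pred_prev, target_prev, weight=beta_weight(sched, t))

        l_ce = ce_loss(out.logits, example.sequence, masked.masked_positions())

        l_ws_acc = l_ws_acc + l_ws * (1.0 / n)
        l_kl_acc = l_kl_acc + l_kl * (1.0 / n)
        l_ce_acc = l_ce_acc + l_ce * (1.0 / n)

    total = l_ws_acc + l_kl_acc + l_ce_acc
    breakdown = LossBreakdown(
        l_ws=l_ws_acc.item(), l_kl=l_kl_acc.item(), l_ce=l_ce_acc.item()
    )
    for name, value in (("L_WS", breakdown.l_ws), ("L_KL", breakdown.l_kl),
                        ("L_CE", breakdown.l_ce)):
        if not np.isfinite(value):
            raise FloatingPointError(f"non-finite loss component {name}")
    model.zero_grad()
    total.backward()
    optimizer.step()
    return breakdown
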