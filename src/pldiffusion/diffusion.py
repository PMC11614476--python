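"""Variance-preserving diffusion on the zero-centroid coordinate subspace.

The forward process q(z_t | x) = N(alpha_t x, sigma_t^2 I) lives in the
linear subspace of coordinate sets whose centroid is the origin, which makes
the construction translation-invariant.  Schedules satisfy the
variance-preserving identity alpha_t^2 + sigma_t^2 = 1 with alpha monotone
non-increasing, alpha(0) ~ 1 and alpha(1) ~ 0.  Generation runs ancestral
sampling from the standard-Gaussian prior at t = 1 down the grid
s(i) = (i-1)/T, t(i) = i/T, using the noise-prediction parameterization
x_hat = (z_t - sigma_t eps_hat) / alpha_t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ligand import LigandGraph
from .sequence import CANONICAL_AA, AminoAcidSequence, MASK_TOKEN

__all__ = [
    "NoiseSchedule",
    "CosineSchedule",
    "LinearLogSNRSchedule",
    "LiteralAlphaSchedule",
    "SCHEDULE_REGISTRY",
    "make_schedule",
    "LatentState",
    "GaussianParams",
    "center",
    "sample_centered_noise",
    "forward_sample",
    "posterior_params",
    "denoised_estimate",
    "reverse_step",
    "sample_complex",
]

_ALPHA_FLOOR = 1e-8


class NoiseSchedule:
    """alpha(t), sigma(t) and the derived transition quantities."""

    def __init__(self, T: int):
        if T < 1:
            raise ValueError("T must be >= 1")
        self.T = int(T)

    def alpha(self, t):  # pragma: no cover - abstract
        raise NotImplementedError

    def sigma(self, t):
        return np.sqrt(np.clip(1.0 - np.asarray(self.alpha(t)) ** 2, 0.0, None))

    def alpha_ts(self, t, s):
        """alpha_{t|s} = alpha_t / alpha_s."""
        return self.alpha(t) / self.alpha(s)

    def sigma2_ts(self, t, s):
        """sigma^2_{t|s} = sigma_t^2 - alpha_{t|s}^2 sigma_s^2."""
        return self.sigma(t) ** 2 - self.alpha_ts(t, s) ** 2 * self.sigma(s) ** 2

    def grid(self, i):
        """(s, t) endpoints of interval i in 1..T."""
        return (i - 1) / self.T, i / self.T


class CosineSchedule(NoiseSchedule):
    """alpha(t) = cos(pi t / 2) (1 - 2 eps0) + eps0, variance-preserving."""

    def __init__(self, T: int, eps0: float = 1e-4):
        super().__init__(T)
        self.eps0 = eps0

    def alpha(self, t):
        t = np.asarray(t, dtype=np.float64)
        return np.cos(np.pi * t / 2.0) * (1.0 - 2.0 * self.eps0) + self.eps0


class LinearLogSNRSchedule(NoiseSchedule):
    """log-SNR linear in t: alpha(t)^2 = sigmoid(lmax + (lmin - lmax) t)."""

    def __init__(self, T: int, logsnr_max: float = 10.0, logsnr_min: float = -10.0):
        super().__init__(T)
        self.logsnr_max = logsnr_max
        self.logsnr_min = logsnr_min

    def alpha(self, t):
        t = np.asarray(t, dtype=np.float64)
        lam = self.logsnr_max + (self.logsnr_min - self.logsnr_max) * t
        return np.sqrt(1.0 / (1.0 + np.exp(-lam)))


class LiteralAlphaSchedule(NoiseSchedule):
    """The literal reading alpha_t = 1 - sigma_t^2 (kept for comparison only).

    This schedule is intentionally NOT in the registry: it violates the
    variance-preserving identity that all registered schedules guarantee,
    and exists so the two readings of the signal/noise relation can be
    compared numerically.
    """

    def __init__(self, T: int, eps0: float = 1e-4):
        super().__init__(T)
        self.eps0 = eps0

    def alpha(self, t):
        return 1.0 - self.sigma(t) ** 2

    def sigma(self, t):
        t = np.asarray(t, dtype=np.float64)
        s2 = (1.0 - 2.0 * self.eps0) * t + self.eps0
        return np.sqrt(s2)


SCHEDULE_REGISTRY: dict[str, type[NoiseSchedule]] = {
    "cosine": CosineSchedule,
    "linear_logsnr": LinearLogSNRSchedule,
}


def make_schedule(T: int, kind: str = "cosine") -> NoiseSchedule:
    try:
        cls = SCHEDULE_REGISTRY[kind]
    except KeyError:
        raise ValueError(
            f"unknown schedule kind {kind!r}; registered: {sorted(SCHEDULE_REGISTRY)}"
        ) from None
    return cls(T)


@dataclass
class LatentState:
    z: np.ndarray  # (r, 3), zero centroid
    t: float

    def __post_init__(self):
        c = self.z.mean(axis=0)
        if np.abs(c).max() > 1e-6:
            raise ValueError(f"latent centroid {c} is not zero")


@dataclass
class GaussianParams:
    mean: np.ndarray  # (r, 3), zero centroid
    var: float

    def __post_init__(self):
        if self.var < -1e-12:
            raise ValueError("negative variance")
        self.var = max(float(self.var), 0.0)


def center(x: np.ndarray) -> np.ndarray:
    """Project coordinates onto the zero-centroid subspace (idempotent)."""
    x = np.asarray(x, dtype=np.float64)
    return x - x.mean(axis=0, keepdims=True)


def sample_centered_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Standard normal in the centered subspace (sample, then center)."""
    return center(rng.standard_normal((n, 3)))


def _require_centered(x: np.ndarray, what: str, auto_center: bool) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if np.abs(x.mean(axis=0)).max() > 1e-6:
        if auto_center:
            return center(x)
        raise ValueError(f"{what} must be centered (pass auto_center=True to project)")
    return x


def forward_sample(
    x: np.ndarray,
    t: float,
    sched: NoiseSchedule,
    seed: int,
    auto_center: bool = False,
    return_noise: bool = False,
):
    """Draw z_t ~ q(z_t | x) = N(alpha_t x, sigma_t^2 I) in the subspace."""
    x = _require_centered(x, "x", auto_center)
    rng = np.random.default_rng(seed)
    eps = sample_centered_noise(rng, x.shape[0])
    z = float(sched.alpha(t)) * x + float(sched.sigma(t)) * eps
    state = LatentState(z=z, t=float(t))
    return (state, eps) if return_noise else state


def posterior_params(
    z_t: LatentState, x: np.ndarray, s: float, t: float, sched: NoiseSchedule
) -> GaussianParams:
    """q(z_s | z_t, x) = N(mu_{t->s}, sigma^2_{t->s} I), s < t.

    mu = (alpha_{t|s} sigma_s^2 / sigma_t^2) z_t
       + (alpha_s sigma_{t|s}^2 / sigma_t^2) x,
    var = sigma_{t|s}^2 sigma_s^2 / sigma_t^2.
    """
    if s >= t:
        raise ValueError(f"posterior requires s < t, got s={s}, t={t}")
    a_ts = float(sched.alpha_ts(t, s))
    s2_ts = float(sched.sigma2_ts(t, s))
    s2_s = float(sched.sigma(s)) ** 2
    s2_t = float(sched.sigma(t)) ** 2
    a_s = float(sched.alpha(s))
    mean = (a_ts * s2_s / s2_t) * z_t.z + (a_s * s2_ts / s2_t) * center(x)
    return GaussianParams(mean=center(mean), var=s2_ts * s2_s / s2_t)


def denoised_estimate(
    z_t: LatentState, eps_hat: np.ndarray, t: float, sched: NoiseSchedule
) -> np.ndarray:
    """x_hat = (z_t - sigma_t eps_hat) / alpha_t, centered."""
    a_t = float(sched.alpha(t))
    if a_t < _ALPHA_FLOOR:
        raise ValueError(f"alpha({t}) = {a_t:g} below {_ALPHA_FLOOR}; estimate ill-conditioned")
    return center((z_t.z - float(sched.sigma(t)) * eps_hat) / a_t)


def reverse_step(
    z_t: LatentState,
    eps_hat: np.ndarray,
    s: float,
    t: float,
    sched: NoiseSchedule,
    seed: int,
    add_noise: bool = True,
) -> LatentState:
    """One ancestral step z_t -> z_s using the noise parameterization.

    The mean (1/alpha_{t|s}) z_t - (sigma_{t|s}^2 / (alpha_{t|s} sigma_t))
    eps_hat is asserted against the posterior mean with x = x_hat
    substituted; the two are algebraically identical.
    """
    if s >= t:
        raise ValueError(f"reverse step requires s < t, got s={s}, t={t}")
    a_ts = float(sched.alpha_ts(t, s))
    s2_ts = float(sched.sigma2_ts(t, s))
    sigma_t = float(sched.sigma(t))
    mean = z_t.z / a_ts - (s2_ts / (a_ts * sigma_t)) * eps_hat
    mean = center(mean)
    post = posterior_params(z_t, denoised_estimate(z_t, eps_hat, t, sched), s, t, sched)
    if not np.allclose(mean, post.mean, atol=1e-8):
        raise AssertionError("reverse-step mean disagrees with the Gaussian posterior mean")
    z_s = mean
    if add_noise:
        rng = np.random.default_rng(seed)
        z_s = mean + np.sqrt(post.var) * sample_centered_noise(rng, mean.shape[0])
    return LatentState(z=center(z_s), t=float(s))


def sample_complex(
    model,
    masked_seq: AminoAcidSequence,
    ligand: LigandGraph,
    seed: int,
    sched: NoiseSchedule | None = None,
    T: int | None = None,
    schedule_kind: str = "cosine",
    denoiser=None,
    decode_noise: bool = False,
    clip_denoised: float | None = 50.0,
) -> tuple[np.ndarray, AminoAcidSequence]:
    """Generate coordinates and a designed sequence by ancestral sampling.

    ``denoiser(z, t) -> eps_hat`` may override the model's noise prediction
    (used e.g. to plug in an oracle); the sequence is decoded at the end by
    argmax over the final logits at masked positions.

    ``clip_denoised`` bounds each coordinate of the implied denoised
    estimate x_hat to +-clip (Angstrom) before the reverse step — the usual
    stabilization against divergence when the noise model is far from
    calibrated (alpha_t is tiny near t = 1, so unchecked estimates explode).
    ``None`` disables it.
    """
    if sched is None:
        sched = make_schedule(T if T is not None else (model.cfg.T if model else 64),
                              schedule_kind)
    rng = np.random.default_rng(seed)
    n_tokens = len(masked_seq) + ligand.n_atoms
    state = LatentState(z=sample_centered_noise(rng, n_tokens), t=1.0)
    logits = None
    for i in range(sched.T, 0, -1):
        s, t = sched.grid(i)
        if denoiser is not None:
            eps_hat = denoiser(state.z, t)
        else:
            out = model(masked_seq, ligand, state.z, t)
            eps_hat = out.eps_hat.numpy()[0]
            logits = out.logits.numpy()[0]
        if not np.isfinite(eps_hat).all():
            raise FloatingPointError(f"non-finite noise prediction at step {i}")
        if clip_denoised is not None:
            x_hat = denoised_estimate(state, eps_hat, t, sched)
            x_hat = center(np.clip(x_hat, -clip_denoised, clip_denoised))
            a_t, s_t = float(sched.alpha(t)), float(sched.sigma(t))
            eps_hat = (state.z - a_t * x_hat) / s_t
        state = reverse_step(state, eps_hat, s, t, sched,
                             seed=int(rng.integers(2**31)))
    a0 = float(sched.alpha(0.0))
    x = state.z / a0
    if decode_noise:
        x = x + (float(sched.sigma(0.0)) / a0) * sample_centered_noise(rng, n_tokens)
    designed = decode_sequence(masked_seq, logits)
    return center(x), designed


def decode_sequence(masked_seq: AminoAcidSequence, logits: np.ndarray | None) -> AminoAcidSequence:
    """Fill masked positions with the argmax amino acid; others unchanged."""
    if logits is None:
        return masked_seq
    residues = list(masked_seq.residues)
    for i, tok in enumerate(residues):
        if tok == MASK_TOKEN:
            residues[i] = CANONICAL_AA[int(np.argmax(logits[i]))]
    return AminoAcidSequence(tuple(residues))
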