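"""Design evaluation statistics: sequence diversity, RMSD, TM-score, CO.

All structural metrics act on 1:1-corresponding coordinate lists (Calpha of
equal-length original and redesigned proteins, optionally plus ligand
atoms).  Diversity is the mean pairwise Levenshtein distance over a set of
sequences.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np

__all__ = [
    "StructurePair",
    "diversity_score",
    "levenshtein",
    "kabsch_rmsd",
    "tm_score",
    "tm_d0",
    "contact_set",
    "contact_overlap",
]


@dataclass(frozen=True)
class StructurePair:
    """Two ordered, equal-length coordinate sets in Angstrom."""

    p: np.ndarray
    p_prime: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.p, dtype=np.float64)
        q = np.asarray(self.p_prime, dtype=np.float64)
        if p.shape != q.shape or p.ndim != 2 or p.shape[1] != 3:
            raise ValueError(f"need matching (N, 3) arrays, got {p.shape} and {q.shape}")
        if p.shape[0] < 1:
            raise ValueError("need at least one point")
        if not (np.isfinite(p).all() and np.isfinite(q).all()):
            raise ValueError("coordinates must be finite")
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "p_prime", q)

    @property
    def n(self) -> int:
        return self.p.shape[0]


def levenshtein(a, b) -> int:
    """Unit-cost edit distance between two sequences (strings or token lists)."""
    sa = a if isinstance(a, str) else "".join(a)
    sb = b if isinstance(b, str) else "".join(b)
    if sa == sb:
        return 0
    return int(edlib.align(sa, sb, task="distance")["editDistance"])


def diversity_score(sequences: list) -> float:
    """Mean pairwise Levenshtein distance over all C(n, 2) pairs."""
    n = len(sequences)
    if n < 2:
        raise ValueError("diversity needs at least two sequences")
    strs = [s if isinstance(s, str) else str(s) for s in sequences]
    total = sum(
        levenshtein(strs[i], strs[j]) for i in range(n - 1) for j in range(i + 1, n)
    )
    return total / (n * (n - 1) / 2)


def _kabsch_rotation(p: np.ndarray, q: np.ndarray, weights: np.ndarray | None = None):
    """Optimal proper rotation R (and centroids) minimizing sum w ||p - R q||^2."""
    w = np.ones(len(p)) if weights is None else np.asarray(weights, dtype=np.float64)
    w = w / w.sum()
    pc = (w[:, None] * p).sum(0)
    qc = (w[:, None] * q).sum(0)
    P = p - pc
    Q = q - qc
    H = (w[:, None] * Q).T @ P
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return R, pc, qc


def kabsch_rmsd(pair: StructurePair) -> tuple[float, np.ndarray, np.ndarray]:
    """Minimum RMSD under rigid superposition, with the optimal (R, t).

    Returns ``(rmsd, R, t)`` such that ``R @ p'_i + t`` best fits ``p_i``;
    R is a proper rotation (det +1).  Degenerate inputs (all points
    coincident) yield the identity rotation by convention.
    """
    p, q = pair.p, pair.p_prime
    if np.allclose(q, q[0]) and np.allclose(p, p[0]):
        R = np.eye(3)
        t = p[0] - q[0]
        return 0.0, R, t
    R, pc, qc = _kabsch_rotation(p, q)
    t = pc - R @ qc
    resid = p - (q @ R.T + t)
    return float(np.sqrt((resid**2).sum(-1).mean())), R, t


def tm_d0(n: int) -> float:
    """Length-dependent TM normalization, floored at 0.5 Angstrom."""
    return max(1.24 * np.cbrt(max(n - 15, 0)) - 1.8, 0.5)


def _tm_value(p, q, R, t, d0):
    d2 = ((p - (q @ R.T + t)) ** 2).sum(-1)
    return float((1.0 / (1.0 + d2 / d0**2)).mean())


def tm_score(pair: StructurePair, d0: float | None = None) -> float:
    """TM-score maximized over rigid motions of the second structure.

    Optimization: Kabsch superposition as initialization, then iterative
    reweighted superposition with weights from the TM kernel derivative,
    plus a few seeded random-rotation restarts; the best value is returned.
    Result lies in (0, 1]; identical structures score 1.
    """
    p, q = pair.p, pair.p_prime
    n = pair.n
    d0 = tm_d0(n) if d0 is None else float(d0)

    def refine(R, t):
        best = _tm_value(p, q, R, t, d0)
        for _ in range(30):
            d2 = ((p - (q @ R.T + t)) ** 2).sum(-1)
            w = 1.0 / (1.0 + d2 / d0**2) ** 2
            R_new, pc, qc = _kabsch_rotation(p, q, weights=w)
            t_new = pc - R_new @ qc
            val = _tm_value(p, q, R_new, t_new, d0)
            if val <= best + 1e-12:
                break
            best, R, t = val, R_new, t_new
        return best

    R0, pc, qc = _kabsch_rotation(p, q)
    candidates = [(R0, pc - R0 @ qc), (np.eye(3), p.mean(0) - q.mean(0))]
    rng = np.random.default_rng(0)
    for _ in range(8):
        A = rng.standard_normal((3, 3))
        Q, _r = np.linalg.qr(A)
        if np.linalg.det(Q) < 0:
            Q[:, 0] *= -1
        candidates.append((Q, p.mean(0) - Q @ q.mean(0)))
    return max(refine(R, t) for R, t in candidates)


def contact_set(coords: np.ndarray, r_c: float, min_separation: int = 1) -> set:
    """Unordered index pairs with ||p_i - p_j|| strictly below the cutoff."""
    coords = np.asarray(coords, dtype=np.float64)
    d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    n = len(coords)
    contacts = set()
    for i in range(n):
        for j in range(i + min_separation, n):
            if j > i and d[i, j] < r_c:
                contacts.add((i, j))
    return contacts


def contact_overlap(pair: StructurePair, r_c: float = 8.0, min_separation: int = 1) -> float:
    """Jaccard overlap of the two contact sets; vacuously 1 when both empty."""
    if pair.n < 2:
        raise ValueError("contact overlap needs at least two points")
    c = contact_set(pair.p, r_c, min_separation)
    c_prime = contact_set(pair.p_prime, r_c, min_separation)
    union = c | c_prime
    if not union:
        return 1.0
    return len(c & c_prime) / len(union)
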