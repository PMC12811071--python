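"""Katz total-effects analysis: pathway counts and the indirect contribution U.

The bipartite incidence matrix B embeds into the symmetric block adjacency

    A = [[0, B], [B^T, 0]]

Walk counts of length l are the entries of A^l.  Discounting walks
geometrically with decay 0 < alpha < 1/lambda (lambda = spectral radius of A)
the series sum_l alpha^l A^l converges to the Katz total-effects matrix

    T = (I - alpha A)^{-1}

whose entries t_ij aggregate pathways of every length between i and j.  The
indirect-pathway contribution

    U = sum_{i != j} (1 - a_ij) t_ij / sum_{i != k} t_ik

is the share of total pairwise effect mass carried by non-adjacent pairs.

Networks here are small (<= a few hundred nodes), so all linear algebra is
dense.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .net_io import BipartiteNetwork, ValidationError

__all__ = [
    "TotalEffects",
    "build_adjacency",
    "spectral_radius",
    "katz_alpha",
    "total_effects",
    "pathway_counts",
    "indirect_contribution",
    "total_effects_analysis",
]

#: rules for choosing the Katz decay from the spectral radius
ALPHA_RULES = ("inverse_shifted", "fraction_of_inverse")


@dataclass(frozen=True)
class TotalEffects:
    """Adjacency, spectral data and Katz total-effects summary for one network."""

    A: np.ndarray
    lam: float
    alpha: float
    T: np.ndarray
    U: float


def build_adjacency(net: BipartiteNetwork, include_isolated: bool = False) -> np.ndarray:
    """Symmetric block adjacency (plants first, then herbivores, each sorted).

    By default nodes with zero realized interactions are dropped, matching the
    phase diagnostics.
    """
    B = net.incidence()
    if not include_isolated:
        B = B[B.sum(axis=1) > 0][:, B.sum(axis=0) > 0]
    np_, nh = B.shape
    n = np_ + nh
    A = np.zeros((n, n), dtype=np.int64)
    A[:np_, np_:] = B
    A[np_:, :np_] = B.T
    return A


def spectral_radius(A: np.ndarray) -> float:
    """Largest eigenvalue of the symmetric adjacency (0 for an empty graph)."""
    A = np.asarray(A, dtype=float)
    if A.size == 0 or not A.any():
        return 0.0
    return float(np.linalg.eigvalsh(A)[-1])


def katz_alpha(lam: float, rule: str = "inverse_shifted") -> float:
    """Decay constant for the Katz series, guaranteeing alpha * lambda < 1.

    ``inverse_shifted`` (default): alpha = 1 / (lambda + 0.01), the smallest
    admissible decay up to the 0.01 shift.  ``fraction_of_inverse``:
    alpha = 0.99 / lambda, a fixed fraction of the convergence bound (requires
    lambda > 0).
    """
    if lam < 0:
        raise ValidationError("spectral radius must be nonnegative")
    if rule == "inverse_shifted":
        return 1.0 / (lam + 0.01)
    if rule == "fraction_of_inverse":
        if lam == 0:
            raise ValidationError("fraction_of_inverse undefined for lambda = 0")
        return 0.99 / lam
    raise ValueError(f"unknown alpha rule {rule!r}; expected one of {ALPHA_RULES}")


def total_effects(A: np.ndarray, alpha: float) -> np.ndarray:
    """T = (I - alpha A)^{-1} via dense linear solve."""
    A = np.asarray(A, dtype=float)
    lam = spectral_radius(A)
    if alpha * lam >= 1.0:
        raise ValidationError(
            f"Katz series diverges: alpha*lambda = {alpha * lam:.6g} >= 1"
        )
    n = A.shape[0]
    return np.linalg.solve(np.eye(n) - alpha * A, np.eye(n))


def pathway_counts(A: np.ndarray, length: int) -> np.ndarray:
    """Number of walks of exactly ``length`` steps between every pair (A^length).

    Walks may revisit nodes and edges.  For bipartite adjacencies, odd lengths
    connect only across sets and even lengths only within sets.
    """
    if length < 1:
        raise ValidationError("pathway length must be >= 1")
    return np.linalg.matrix_power(np.asarray(A, dtype=np.int64), length)


def indirect_contribution(A: np.ndarray, T: np.ndarray) -> float:
    """Share of off-diagonal total-effect mass on non-adjacent pairs (Eq. U)."""
    A = np.asarray(A, dtype=float)
    T = np.asarray(T, dtype=float)
    off = ~np.eye(A.shape[0], dtype=bool)
    denom = T[off].sum()
    if denom <= 0:
        raise ValidationError("indirect contribution undefined: no pairwise effects")
    numer = ((1.0 - A) * T)[off].sum()
    return float(numer / denom)


def total_effects_analysis(
    net: BipartiteNetwork,
    alpha_rule: str = "inverse_shifted",
    include_isolated: bool = False,
) -> TotalEffects:
    """Run the full chain A -> lambda -> alpha -> T -> U for one network."""
    A = build_adjacency(net, include_isolated=include_isolated)
    lam = spectral_radius(A)
    alpha = katz_alpha(lam, rule=alpha_rule)
    T = total_effects(A, alpha)
    U = indirect_contribution(A, T)
    return TotalEffects(A=A, lam=lam, alpha=alpha, T=T, U=U)
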