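"""Reversible nucleotide substitution models (JC69, HKY85).

Rate matrices are scaled so one unit of branch length equals one expected
substitution per site at equilibrium; transition probabilities come from the
spectral decomposition of the symmetrized generator, which also feeds the
MCMC kernel.  State order is A, C, G, T.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SubstitutionModel", "jc69", "hky85", "ALPHABET"]

ALPHABET = "ACGT"


@dataclass(frozen=True)
class SubstitutionModel:
    name: str
    rate_matrix: np.ndarray  # 4x4 generator Q, rows sum to 0, mean rate 1
    freqs: np.ndarray  # equilibrium frequencies

    def __post_init__(self) -> None:
        q = np.asarray(self.rate_matrix, dtype=float)
        pi = np.asarray(self.freqs, dtype=float)
        if q.shape != (4, 4) or pi.shape != (4,):
            raise ValueError("expected a 4x4 rate matrix and 4 frequencies")
        if not np.isclose(pi.sum(), 1.0):
            raise ValueError("equilibrium frequencies must sum to 1")
        if not np.allclose(q.sum(axis=1), 0.0, atol=1e-12):
            raise ValueError("rate matrix rows must sum to 0")
        # detailed balance check: pi_i q_ij == pi_j q_ji
        if not np.allclose(pi[:, None] * q, (pi[:, None] * q).T, atol=1e-10):
            raise ValueError("rate matrix is not reversible with the given frequencies")
        object.__setattr__(self, "rate_matrix", q)
        object.__setattr__(self, "freqs", pi)

    @property
    def eigensystem(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(eigenvalues, U, U^-1) with Q = U diag(w) U^-1, computed stably
        via the pi-symmetrized form."""
        pi = self.freqs
        s = np.sqrt(pi)
        b = (s[:, None] * self.rate_matrix) / s[None, :]
        w, v = np.linalg.eigh((b + b.T) / 2.0)
        u = v / s[:, None]
        uinv = v.T * s[None, :]
        return w, u, uinv

    def transition_matrix(self, d: float) -> np.ndarray:
        """P(d) = exp(Q d) for branch length ``d`` in substitutions/site."""
        if d < 0:
            raise ValueError("branch length must be non-negative")
        w, u, uinv = self.eigensystem
        p = (u * np.exp(w * d)) @ uinv
        np.clip(p, 0.0, 1.0, out=p)
        return p / p.sum(axis=1, keepdims=True)


def jc69() -> SubstitutionModel:
    """Jukes-Cantor: equal frequencies, one exchange rate."""
    q = np.full((4, 4), 1.0 / 3.0)
    np.fill_diagonal(q, -1.0)
    return SubstitutionModel("JC69", q, np.full(4, 0.25))


def hky85(kappa: float = 2.0, freqs=(0.25, 0.25, 0.25, 0.25)) -> SubstitutionModel:
    """HKY85 with transition/transversion ratio ``kappa`` and base frequencies
    in A, C, G, T order."""
    pi = np.asarray(freqs, dtype=float)
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    q = np.zeros((4, 4))
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T
    for i in range(4):
        for j in range(4):
            if i != j:
                q[i, j] = pi[j] * (kappa if (i, j) in transitions else 1.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    mean_rate = -(pi * np.diag(q)).sum()
    return SubstitutionModel("HKY85", q / mean_rate, pi)
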