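"""GY94 codon rate matrices over the 61 sense codons.

The instantaneous rate of a single-nucleotide codon change i -> j is
proportional to the target codon frequency pi_j, multiplied by kappa for
transitions and by omega for nonsynonymous changes; multi-step changes
have rate zero.  Matrices are scaled so the expected number of
substitutions per codon site per unit time at stationarity equals one,
making branch lengths directly comparable between simulation and
inference.  The chain is time-reversible, which is exploited for stable
transition probabilities via a symmetric eigendecomposition.
"""

from __future__ import annotations

import numpy as np

from .codata import (
    BASES,
    N_CODONS,
    SENSE_CODONS,
    SINGLE_STEP_I,
    SINGLE_STEP_J,
    SINGLE_STEP_NONSYN,
    SINGLE_STEP_TS,
)
from .errors import InputError

_PI_FLOOR = 1e-10


def f3x4_frequencies(position_freqs: np.ndarray) -> np.ndarray:
    """Codon frequencies from per-position nucleotide compositions (F3x4).

    ``position_freqs`` is a 3x4 array of nucleotide frequencies (T, C, A, G
    order) at the three codon positions.  Stop codons are excluded and the
    remainder renormalized.
    """
    f = np.asarray(position_freqs, dtype=float)
    if f.shape != (3, 4):
        raise InputError("position_freqs must be 3x4 (positions x TCAG)")
    if np.any(f < 0) or not np.allclose(f.sum(axis=1), 1.0, atol=1e-8):
        raise InputError("each position's nucleotide frequencies must sum to 1")
    pi = np.array(
        [f[0, BASES.index(c[0])] * f[1, BASES.index(c[1])] * f[2, BASES.index(c[2])]
         for c in SENSE_CODONS]
    )
    pi = np.maximum(pi, _PI_FLOOR)
    return pi / pi.sum()


def empirical_position_freqs(codon_index_matrix: np.ndarray) -> np.ndarray:
    """3x4 per-position nucleotide frequencies observed in coded sequences."""
    counts = np.full((3, 4), 0.0)
    codes = codon_index_matrix[codon_index_matrix >= 0]
    for pos in range(3):
        for b in range(4):
            counts[pos, b] = sum(
                1 for c in codes if SENSE_CODONS[c][pos] == BASES[b]
            )
    counts += 0.5  # avoid zero frequencies
    return counts / counts.sum(axis=1, keepdims=True)


def build_rate_matrix(
    kappa: float, omega: float, pi: np.ndarray, *, scale: bool = True
) -> np.ndarray:
    """GY94 rate matrix; rows sum to zero; mean rate 1 at stationarity if scaled."""
    if kappa <= 0:
        raise InputError("kappa must be > 0")
    if omega < 0:
        raise InputError("omega must be >= 0")
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (N_CODONS,) or np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-6:
        raise InputError("pi must be 61 non-negative frequencies summing to 1")
    rates = pi[SINGLE_STEP_J].copy()
    rates[SINGLE_STEP_TS] *= kappa
    rates[SINGLE_STEP_NONSYN] *= omega
    Q = np.zeros((N_CODONS, N_CODONS))
    Q[SINGLE_STEP_I, SINGLE_STEP_J] = rates
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if scale:
        mu = -float(np.dot(pi, np.diag(Q)))
        if mu > 0:
            Q /= mu
    return Q


class SpectralQ:
    """Eigendecomposition of a reversible Q for fast P(t) = exp(Qt).

    With D = diag(pi), B = D^{1/2} Q D^{-1/2} is symmetric; eigh gives
    B = V diag(lam) V', so P(t) = D^{-1/2} V exp(lam t) V' D^{1/2}.
    """

    def __init__(self, kappa: float, omega: float, pi: np.ndarray, *, scale: bool = True):
        self.kappa, self.omega = float(kappa), float(omega)
        self.pi = np.asarray(pi, dtype=float)
        Q = build_rate_matrix(kappa, omega, self.pi, scale=scale)
        self.Q = Q
        #: expected substitutions per codon site per unit time at stationarity
        self.rate = -float(np.dot(self.pi, np.diag(Q)))
        sq = np.sqrt(np.maximum(self.pi, _PI_FLOOR))
        B = (sq[:, None] * Q) / sq[None, :]
        B = 0.5 * (B + B.T)
        lam, V = np.linalg.eigh(B)
        self.lam = lam
        self.left = V.T * sq[None, :]       # V' D^{1/2}
        self.right = (V.T / sq[None, :]).T  # D^{-1/2} V

    def transition_matrix(self, t: float) -> np.ndarray:
        if t < 0:
            raise InputError("branch length must be >= 0")
        P = (self.right * np.exp(self.lam * t)) @ self.left
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


def mean_rate(kappa: float, omega: float, pi: np.ndarray) -> float:
    """Expected substitutions per codon site per unit time of the unscaled Q."""
    Q = build_rate_matrix(kappa, omega, pi, scale=False)
    return -float(np.dot(np.asarray(pi, float), np.diag(Q)))


def transition_matrix(Q: np.ndarray, t: float, pi: np.ndarray | None = None) -> np.ndarray:
    """P(t) = exp(Qt) for a valid rate matrix and t >= 0."""
    if t < 0:
        raise InputError("branch length must be >= 0")
    Q = np.asarray(Q, dtype=float)
    if pi is None:
        # stationary distribution from the left null vector of Q
        w, vl = np.linalg.eig(Q.T)
        k = int(np.argmin(np.abs(w)))
        pi = np.real(vl[:, k])
        pi = np.abs(pi) / np.abs(pi).sum()
    sq = np.sqrt(np.maximum(np.asarray(pi, dtype=float), _PI_FLOOR))
    B = (sq[:, None] * Q) / sq[None, :]
    B = 0.5 * (B + B.T)
    lam, V = np.linalg.eigh(B)
    P = ((V / sq[:, None]) * np.exp(lam * t)) @ (V.T * sq[None, :])
    np.clip(P, 0.0, None, out=P)
    P /= P.sum(axis=1, keepdims=True)
    return P
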