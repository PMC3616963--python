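"""General time-reversible (GTR) nucleotide model with discrete-Gamma rates.

Shared between the sequence simulator and the likelihood core.  States are
ordered A, C, G, T; exchangeabilities are ordered AC, AG, AT, CG, CT, GT.
The rate matrix is always rescaled to one expected substitution per site
per unit branch length, so branch lengths are in substitutions/site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy.special import gammainc, gammaincinv

DNA = "ACGT"
_PAIRS = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]


@dataclass
class GTRParams:
    """GTR(+Gamma) model parameters.

    exchangeabilities: 6 positive reals (AC, AG, AT, CG, CT, GT); the
    likelihood is invariant to their overall scale (GT conventionally 1).
    gamma_shape None means no among-site rate variation.
    """

    exchangeabilities: np.ndarray = field(
        default_factory=lambda: np.ones(6))
    base_freqs: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))
    gamma_shape: Optional[float] = None
    n_categories: int = 4

    def __post_init__(self) -> None:
        self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float)
        self.base_freqs = np.asarray(self.base_freqs, dtype=float)
        if self.exchangeabilities.shape != (6,):
            raise ValueError("need 6 exchangeabilities (AC,AG,AT,CG,CT,GT)")
        if np.any(self.exchangeabilities <= 0):
            raise ValueError("exchangeabilities must be positive")
        if self.base_freqs.shape != (4,):
            raise ValueError("need 4 base frequencies (A,C,G,T)")
        if np.any(self.base_freqs <= 0):
            raise ValueError("base frequencies must be positive")
        if abs(self.base_freqs.sum() - 1.0) > 1e-12:
            raise ValueError("base frequencies must sum to 1")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma shape must be positive")

    def rate_categories(self) -> np.ndarray:
        if self.gamma_shape is None:
            return np.ones(1)
        return discrete_gamma_rates(self.gamma_shape, self.n_categories)


def discrete_gamma_rates(shape: float, n_categories: int = 4) -> np.ndarray:
    """Mean-of-quantile-bin discretization of Gamma(shape, 1/shape).

    Bin boundaries are the i/k quantiles; the category rate is the mean of
    the distribution within each bin, so the rates average exactly 1.
    """
    a = float(shape)
    k = int(n_categories)
    probs = np.arange(1, k) / k
    cuts = gammaincinv(a, probs) / a          # quantiles of mean-1 gamma
    edges = np.concatenate([[0.0], cuts, [np.inf]])
    upper = gammainc(a + 1, a * edges[1:])
    lower = gammainc(a + 1, a * edges[:-1])
    rates = (upper - lower) * k
    return rates / rates.mean()


def rate_matrix(params: GTRParams) -> np.ndarray:
    """Scaled GTR rate matrix Q with stationary distribution base_freqs."""
    q = np.zeros((4, 4))
    for (i, j), s in zip(_PAIRS, params.exchangeabilities):
        q[i, j] = s * params.base_freqs[j]
        q[j, i] = s * params.base_freqs[i]
    np.fill_diagonal(q, -q.sum(axis=1))
    mu = -np.dot(params.base_freqs, np.diag(q))
    if mu <= 0:
        raise ValueError("degenerate rate matrix")
    return q / mu


def eigendecompose(params: GTRParams) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Spectral decomposition Q = U diag(lam) V via symmetrization.

    Returns (lam, U, V) with V = U^-1; exact because GTR is reversible.
    """
    q = rate_matrix(params)
    pi = params.base_freqs
    d = np.sqrt(pi)
    sym = (q * d[:, None]) / d[None, :]
    sym = 0.5 * (sym + sym.T)
    lam, w = np.linalg.eigh(sym)
    u = w / d[:, None]
    v = w.T * d[None, :]
    return lam, u, v


def transition_matrices(lam: np.ndarray, u: np.ndarray, v: np.ndarray,
                        lengths: np.ndarray, rates: np.ndarray) -> np.ndarray:
    """P(t*r) for every (branch, rate category): shape (n_branch, n_cat, 4, 4)."""
    lengths = np.asarray(lengths, dtype=float)
    t_eff = lengths[:, None] * np.asarray(rates)[None, :]
    e = np.exp(t_eff[:, :, None] * lam[None, None, :])
    p = np.einsum("ik,bck,kj->bcij", u, e, v)
    np.clip(p, 0.0, None, out=p)
    # renormalize rows against accumulated round-off
    p /= p.sum(axis=3, keepdims=True)
    return p
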