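"""Amino-acid substitution process: LG exchangeabilities with discrete-gamma
among-site rate variation.

The rate matrix is built as Q_ij = S_ij * pi_j (i != j), with the diagonal set
so rows sum to zero, and globally rescaled so the expected substitution rate at
stationarity is one — branch lengths are then expected substitutions per site.
Rate heterogeneity uses K equal-probability gamma categories, each category
represented by its conditional mean (the usual discrete-gamma construction),
renormalized so the category rates average exactly one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaincc, gammainc
from scipy.stats import gamma as gamma_dist

from ._lg_data import AMINO_ACIDS, LG_FREQS, lg_exchangeability

GAP_CODE = -1

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


def encode_residue(ch: str) -> int:
    """Map a residue character to its state index; gaps/ambiguity -> GAP_CODE."""
    return _AA_INDEX.get(ch.upper(), GAP_CODE)


def discrete_gamma_rates(alpha: float, n_categories: int = 4) -> np.ndarray:
    """Mean rates of K equal-probability categories of a Gamma(alpha, 1/alpha).

    The conditional mean within each inter-quantile slice is computed from the
    regularized incomplete gamma function; rates are renormalized to mean 1.
    """
    if alpha <= 0:
        raise ValueError(f"gamma shape must be positive, got {alpha}")
    K = n_categories
    if K == 1:
        return np.ones(1)
    # category boundaries in x (rate) units for Gamma(shape=a, scale=1/a)
    probs = np.arange(1, K) / K
    cuts = gamma_dist.ppf(probs, alpha, scale=1.0 / alpha)
    x = np.concatenate(([0.0], cuts * alpha, [np.inf]))  # standard-gamma units
    # E[X | slice] * P(slice) = (a/a) * (P(a+1, x2) - P(a+1, x1)) for scale 1/a
    seg = gammainc(alpha + 1.0, x[1:]) - gammainc(alpha + 1.0, x[:-1])
    seg[-1] = gammaincc(alpha + 1.0, x[-2])
    rates = seg * K
    return rates / rates.mean()


@dataclass
class LGGammaModel:
    """LG + discrete-gamma substitution model.

    Parameters
    ----------
    alpha : gamma shape of among-site rate variation (>0).
    n_categories : number of equal-weight discrete rate categories.
    """

    alpha: float = 1.0
    n_categories: int = 4
    exchangeability: np.ndarray = field(default_factory=lg_exchangeability)
    freqs: np.ndarray = field(default_factory=lambda: LG_FREQS.copy())

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.n_categories < 1:
            raise ValueError("n_categories must be >= 1")
        pi = np.asarray(self.freqs, dtype=float)
        if abs(pi.sum() - 1.0) > 1e-8:
            raise ValueError("stationary frequencies must sum to 1")
        self._decompose()

    def _decompose(self) -> None:
        pi = self.freqs
        S = self.exchangeability
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        # normalize expected rate to 1 substitution/site
        scale = -np.dot(pi, np.diag(Q))
        Q /= scale
        self.rate_matrix = Q
        # reversible Q is symmetric in the pi^{1/2} basis
        sq = np.sqrt(pi)
        B = (Q * sq[:, None]) / sq[None, :]
        B = 0.5 * (B + B.T)
        w, U = np.linalg.eigh(B)
        self._eigvals = w
        self._left = U.T * sq[None, :]          # U^T diag(sqrt(pi))
        self._right = U / sq[:, None]           # diag(1/sqrt(pi)) U

    @property
    def category_rates(self) -> np.ndarray:
        return discrete_gamma_rates(self.alpha, self.n_categories)

    @property
    def category_weights(self) -> np.ndarray:
        K = self.n_categories
        return np.full(K, 1.0 / K)

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt) via the symmetric eigendecomposition."""
        if not np.isfinite(t) or t < 0:
            raise ValueError(f"branch length must be finite and >= 0, got {t}")
        P = (self._right * np.exp(self._eigvals * t)[None, :]) @ self._left
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def with_alpha(self, alpha: float) -> "LGGammaModel":
        return LGGammaModel(alpha=alpha, n_categories=self.n_categories,
                            exchangeability=self.exchangeability,
                            freqs=self.freqs)
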