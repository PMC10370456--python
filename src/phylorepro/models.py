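"""Nucleotide substitution models (HKY, GTR) with discrete-gamma rates.

State order is (A, C, G, T).  Rate matrices are normalized to one expected
substitution per unit branch length, so branch lengths are in expected
substitutions per site.  Transition matrices are computed from the
eigendecomposition of the reversible generator, symmetrized with the usual
pi^{1/2} similarity transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

__all__ = ["SubstModel", "hky", "gtr", "jc", "discrete_gamma_rates"]

NUCS = "ACGT"
_TRANSITIONS = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T


def discrete_gamma_rates(shape: float, n_categories: int) -> np.ndarray:
    """Mean rate of each of ``n_categories`` equal-probability bins of a
    Gamma(shape, rate=shape) distribution (mean 1) — the "+G" convention.
    """
    if shape <= 0:
        raise ValueError("gamma shape must be positive")
    if n_categories < 1:
        raise ValueError("need at least one rate category")
    if n_categories == 1:
        return np.ones(1)
    probs = np.arange(1, n_categories) / n_categories
    cuts = gamma_dist.ppf(probs, a=shape, scale=1.0 / shape)
    upper = np.concatenate([cuts, [np.inf]])
    lower = np.concatenate([[0.0], cuts])
    # E[X; bin] = P_{a+1}(shape * x) evaluated at the bin edges (mean-1 gamma)
    mass = gammainc(shape + 1, shape * upper) - gammainc(shape + 1, shape * lower)
    rates = n_categories * mass
    return rates / rates.mean()


@dataclass(frozen=True)
class SubstModel:
    """A reversible nucleotide substitution model.

    Parameters
    ----------
    kind : {"HKY", "GTR"}
    base_freqs : array-like of 4 positive frequencies summing to 1 (A,C,G,T).
    kappa : transition/transversion *rate* ratio (HKY only).
    exchangeabilities : 6 GTR exchangeabilities in the order
        (AC, AG, AT, CG, CT, GT) (GTR only).
    gamma_shape : shape of the discrete-gamma rate heterogeneity, or None
        for a single homogeneous rate class.
    n_categories : number of discrete gamma categories (default 4).
    """

    kind: str
    base_freqs: tuple[float, float, float, float]
    kappa: float | None = None
    exchangeabilities: tuple[float, ...] | None = None
    gamma_shape: float | None = None
    n_categories: int = 4

    def __post_init__(self):
        pi = np.asarray(self.base_freqs, dtype=float)
        if pi.shape != (4,) or np.any(pi <= 0):
            raise ValueError("base_freqs must be 4 positive values")
        if abs(pi.sum() - 1.0) > 1e-8:
            raise ValueError("base_freqs must sum to 1")
        object.__setattr__(self, "base_freqs", tuple(pi / pi.sum()))
        if self.kind == "HKY":
            if self.kappa is None or self.kappa <= 0:
                raise ValueError("HKY requires a positive kappa")
        elif self.kind == "GTR":
            if self.exchangeabilities is None or len(self.exchangeabilities) != 6:
                raise ValueError("GTR requires 6 exchangeabilities")
            if any(x <= 0 for x in self.exchangeabilities):
                raise ValueError("exchangeabilities must be positive")
        else:
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive or None")

    # ------------------------------------------------------------------ #

    @property
    def pi(self) -> np.ndarray:
        return np.asarray(self.base_freqs)

    def category_rates(self) -> np.ndarray:
        if self.gamma_shape is None:
            return np.ones(1)
        return discrete_gamma_rates(self.gamma_shape, self.n_categories)

    def rate_matrix(self) -> np.ndarray:
        """Generator Q, normalized to mean rate 1 (-sum pi_i Q_ii = 1)."""
        pi = self.pi
        R = np.zeros((4, 4))
        if self.kind == "HKY":
            for i in range(4):
                for j in range(4):
                    if i != j:
                        R[i, j] = self.kappa if (i, j) in _TRANSITIONS else 1.0
        else:
            ex = self.exchangeabilities
            pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
            for (i, j), x in zip(pairs, ex):
                R[i, j] = R[j, i] = x
        Q = R * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -(pi * np.diag(Q)).sum()
        return Q / mu

    def eigen(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(eigenvalues, U, U^{-1}) of Q such that P(t) = U diag(e^{l t}) U^{-1}.

        Computed via the symmetric similarity transform, so the decomposition
        is numerically stable for any reversible model.
        """
        pi = self.pi
        Q = self.rate_matrix()
        sq = np.sqrt(pi)
        S = (Q * sq[:, None]) / sq[None, :]
        S = (S + S.T) / 2.0
        evals, V = np.linalg.eigh(S)
        U = V / sq[:, None]  # diag(1/sqrt(pi)) @ V
        Uinv = (V * sq[:, None]).T  # V.T @ diag(sqrt(pi))
        return evals, U, Uinv

    def transition_matrix(self, d: float, rate_multiplier: float = 1.0) -> np.ndarray:
        """P(d) = exp(Q d r): probability of state j after branch length d."""
        if d < 0:
            raise ValueError(f"branch length must be non-negative, got {d}")
        evals, U, Uinv = self.eigen()
        P = (U * np.exp(evals * d * rate_multiplier)[None, :]) @ Uinv
        return np.clip(P, 0.0, None)

    def with_params(self, **kwargs) -> "SubstModel":
        return replace(self, **kwargs)


def hky(kappa: float, base_freqs=(0.25, 0.25, 0.25, 0.25),
        gamma_shape: float | None = None, n_categories: int = 4) -> SubstModel:
    return SubstModel("HKY", tuple(base_freqs), kappa=kappa,
                      gamma_shape=gamma_shape, n_categories=n_categories)


def gtr(exchangeabilities, base_freqs=(0.25, 0.25, 0.25, 0.25),
        gamma_shape: float | None = None, n_categories: int = 4) -> SubstModel:
    return SubstModel("GTR", tuple(base_freqs),
                      exchangeabilities=tuple(exchangeabilities),
                      gamma_shape=gamma_shape, n_categories=n_categories)


def jc() -> SubstModel:
    """Jukes-Cantor: HKY with kappa = 1 and uniform base frequencies."""
    return hky(kappa=1.0)
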