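"""Nucleotide substitution models of the GTR family.

All supported families (JC69, K80, HKY85, SYM, TVM, GTR) are
parameterized as special cases of the general time-reversible model:
symmetric exchangeabilities over the six unordered base pairs (order
AC, AG, AT, CG, CT, GT) combined with stationary base frequencies.
SYM, K80 and JC69 fix equal frequencies; TVM ties the two transition
rates (AG = CT).  Rate matrices are scaled to one expected substitution
per site per unit time.  Among-site rate variation uses a discrete gamma
with mean-of-slice category rates, optionally mixed with a proportion of
invariant sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

__all__ = ["SubstitutionModel", "BASES", "empirical_frequencies"]

BASES = "ACGT"
_PAIRS = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]  # AC AG AT CG CT GT
_EQUAL = np.full(4, 0.25)

_FAMILIES = {"JC69", "K80", "HKY85", "SYM", "TVM", "GTR"}


@dataclass(frozen=True)
class SubstitutionModel:
    """A GTR-family model with optional +G and +I rate heterogeneity.

    Parameters
    ----------
    family:
        One of JC69, K80, HKY85, SYM, TVM, GTR.
    rates:
        Exchangeabilities (AC, AG, AT, CG, CT, GT); interpretation depends
        on the family (see :meth:`exchangeabilities`).
    freqs:
        Stationary base frequencies (ACGT); forced equal for JC69/K80/SYM.
    alpha:
        Gamma shape for among-site rate variation (None = no +G).
    n_categories:
        Number of discrete gamma categories (default 4).
    p_inv:
        Proportion of invariant sites (0 = no +I).
    """

    family: str = "JC69"
    rates: tuple = ()
    freqs: tuple = (0.25, 0.25, 0.25, 0.25)
    alpha: float | None = None
    n_categories: int = 4
    p_inv: float = 0.0

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")
        f = np.asarray(self.freqs, float)
        if f.shape != (4,) or not np.isclose(f.sum(), 1.0) or (f <= 0).any():
            raise ValueError("frequencies must be 4 positive values summing to 1")
        if not 0.0 <= self.p_inv < 1.0:
            raise ValueError("p_inv must be in [0, 1)")
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("gamma shape must be positive")

    # -- constructors ------------------------------------------------------

    @classmethod
    def jc69(cls, **kw) -> "SubstitutionModel":
        return cls(family="JC69", **kw)

    @classmethod
    def k80(cls, kappa: float = 2.0, **kw) -> "SubstitutionModel":
        return cls(family="K80", rates=(kappa,), **kw)

    @classmethod
    def hky85(cls, kappa: float = 2.0, freqs=(0.25, 0.25, 0.25, 0.25), **kw):
        return cls(family="HKY85", rates=(kappa,), freqs=tuple(freqs), **kw)

    @classmethod
    def sym(cls, rates=(1, 1, 1, 1, 1, 1), **kw) -> "SubstitutionModel":
        return cls(family="SYM", rates=tuple(rates), **kw)

    @classmethod
    def tvm(cls, rates=(1, 1, 1, 1), freqs=(0.25, 0.25, 0.25, 0.25), **kw):
        """TVM: free transversions (AC, AT, CG, GT), tied transitions."""
        return cls(family="TVM", rates=tuple(rates), freqs=tuple(freqs), **kw)

    @classmethod
    def gtr(cls, rates=(1, 1, 1, 1, 1, 1), freqs=(0.25, 0.25, 0.25, 0.25), **kw):
        return cls(family="GTR", rates=tuple(rates), freqs=tuple(freqs), **kw)

    # -- matrices ----------------------------------------------------------

    def exchangeabilities(self) -> np.ndarray:
        """The six symmetric exchangeability parameters (AC..GT)."""
        r = np.asarray(self.rates, float)
        if self.family == "JC69":
            return np.ones(6)
        if self.family in ("K80", "HKY85"):
            kappa = float(r[0]) if r.size else 2.0
            out = np.ones(6)
            out[1] = out[4] = kappa  # AG, CT transitions
            return out
        if self.family == "TVM":
            if r.size not in (4, 5):
                raise ValueError("TVM takes 4 transversion rates (+ optional transition rate)")
            ts = float(r[4]) if r.size == 5 else 1.0
            return np.array([r[0], ts, r[1], r[2], ts, r[3]], float)
        if r.size != 6:
            raise ValueError(f"{self.family} takes 6 exchangeabilities")
        return r

    @property
    def frequencies(self) -> np.ndarray:
        if self.family in ("JC69", "K80", "SYM"):
            return _EQUAL.copy()
        return np.asarray(self.freqs, float)

    def rate_matrix(self) -> np.ndarray:
        """Scaled instantaneous rate matrix Q (mean rate 1)."""
        R = np.zeros((4, 4))
        ex = self.exchangeabilities()
        for (i, j), r in zip(_PAIRS, ex):
            R[i, j] = R[j, i] = r
        pi = self.frequencies
        Q = R * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -(pi * np.diag(Q)).sum()
        return Q / mu

    def _eigen(self):
        return _eigen_cached(self)

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows are 'from', columns 'to'."""
        w, sq, U = self._eigen()
        E = U * np.exp(w * max(t, 0.0))[None, :]
        P = (E @ U.T) * (sq[None, :] / sq[:, None])
        P = np.clip(P, 0.0, None)
        return P / P.sum(axis=1, keepdims=True)

    # -- rate heterogeneity ------------------------------------------------

    def category_rates(self) -> tuple[np.ndarray, np.ndarray]:
        """Discrete-gamma category rates and probabilities (mean rates).

        Without +G this is a single category of rate 1.  The +I mixture is
        handled by the likelihood/simulation code, not here.
        """
        if self.alpha is None:
            return np.array([1.0]), np.array([1.0])
        n, a = self.n_categories, float(self.alpha)
        cuts = gamma_dist.ppf(np.arange(1, n) / n, a, scale=1.0 / a)
        bounds = np.concatenate([[0.0], cuts, [np.inf]])
        # mean of a mean-1 gamma over each slice: n * [I(a+1, a*hi) - I(a+1, a*lo)]
        upper = gammainc(a + 1, a * bounds[1:])
        lower = gammainc(a + 1, a * bounds[:-1])
        rates = n * (upper - lower)
        return rates, np.full(n, 1.0 / n)


@lru_cache(maxsize=64)
def _eigen_cached(model: SubstitutionModel):
    """Symmetric-form eigendecomposition of the reversible Q (cached)."""
    pi = model.frequencies
    sq = np.sqrt(pi)
    Q = model.rate_matrix()
    B = (Q * sq[:, None]) / sq[None, :]
    B = (B + B.T) / 2  # enforce symmetry against rounding
    w, U = np.linalg.eigh(B)
    return w, sq, U


def empirical_frequencies(aln) -> np.ndarray:
    """Base frequencies from unambiguous characters of an alignment."""
    from . import iupac

    M = aln.matrix
    npc = iupac.popcount(M)
    counts = np.array([((M == m) & (npc == 1)).sum() for m in (1, 2, 4, 8)], float)
    if counts.sum() == 0:
        return _EQUAL.copy()
    return counts / counts.sum()
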