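"""Amino-acid substitution models and discrete-gamma rate machinery.

The package works with time-reversible 20-state models defined by a symmetric
exchangeability matrix ``S`` and equilibrium frequencies ``pi``.  The
instantaneous rate matrix is ``Q = S @ diag(pi)`` with the diagonal set so rows
sum to zero, normalised so that one unit of branch length equals one expected
substitution per site at equilibrium.  Transition probabilities ``P(t)`` are
obtained from the symmetric eigendecomposition of
``diag(sqrt(pi)) Q diag(1/sqrt(pi))``, which is numerically stable and lets a
single decomposition serve every branch length.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


def _expand_lower_triangle(values: np.ndarray, n: int = 20) -> np.ndarray:
    mat = np.zeros((n, n))
    k = 0
    for i in range(1, n):
        for j in range(i):
            mat[i, j] = mat[j, i] = values[k]
            k += 1
    if k != len(values):
        raise ValueError(f"expected {n * (n - 1) // 2} exchangeabilities, got {len(values)}")
    return mat


@dataclass(frozen=True)
class SubstitutionModel:
    """Time-reversible amino-acid model (exchangeabilities + frequencies)."""

    name: str
    exchangeabilities: np.ndarray
    frequencies: np.ndarray
    _eig: tuple = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self):
        S = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.frequencies, dtype=float)
        if S.shape != (20, 20):
            raise ValueError("exchangeability matrix must be 20x20")
        if not np.allclose(S, S.T, atol=1e-9):
            raise ValueError("exchangeability matrix must be symmetric")
        if np.any(S < 0) or np.any(pi <= 0):
            raise ValueError("exchangeabilities must be >= 0 and frequencies > 0")
        pi = pi / pi.sum()
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        # normalise: expected rate at equilibrium = -sum_i pi_i Q_ii = 1
        scale = -np.dot(pi, np.diag(Q))
        Q = Q / scale
        object.__setattr__(self, "frequencies", pi)
        object.__setattr__(self, "rate_matrix", Q)
        # symmetric form B = D^{1/2} Q D^{-1/2}
        sqrt_pi = np.sqrt(pi)
        B = (Q / sqrt_pi[None, :]) * sqrt_pi[:, None]
        B = (B + B.T) / 2.0
        lam, E = np.linalg.eigh(B)
        # P(t) = U @ diag(exp(lam t)) @ V with U = D^{-1/2} E, V = E.T D^{1/2}
        U = E / sqrt_pi[:, None]
        V = E.T * sqrt_pi[None, :]
        object.__setattr__(self, "_eig", (lam, U, V))

    # -- transition probabilities ---------------------------------------------------

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t): probability of state j after branch length t, given state i."""
        if t < 0:
            raise ValueError("branch length must be >= 0")
        lam, U, V = self._eig
        P = (U * np.exp(lam * t)[None, :]) @ V
        P = np.clip(P, 0.0, None)
        return P / P.sum(axis=1, keepdims=True)

    def transition_rows(self, states: np.ndarray, ts: np.ndarray) -> np.ndarray:
        """Row ``P(ts[k])[states[k], :]`` for each k, vectorised over sites."""
        lam, U, V = self._eig
        # (n,20) = (U[states] * exp(outer(ts, lam))) @ V
        rows = (U[states, :] * np.exp(np.outer(ts, lam))) @ V
        rows = np.clip(rows, 0.0, None)
        return rows / rows.sum(axis=1, keepdims=True)

    # -- sampling -------------------------------------------------------------------

    def sample_equilibrium(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.choice(20, size=n, p=self.frequencies)

    # -- constructors ---------------------------------------------------------------

    @classmethod
    def lg(cls) -> "SubstitutionModel":
        """The Le & Gascuel (2008) empirical model (packaged constants)."""
        with resources.files("cpakit.data").joinpath("lg_model.json").open() as fh:
            data = json.load(fh)
        if data["order"] != list(AMINO_ACIDS):
            raise ValueError("packaged LG model uses an unexpected alphabet order")
        S = _expand_lower_triangle(np.asarray(data["exchangeabilities_lower_triangle"]))
        return cls("LG", S, np.asarray(data["frequencies"]))

    @classmethod
    def poisson(cls) -> "SubstitutionModel":
        """Uniform-rate, uniform-frequency fallback model."""
        S = np.ones((20, 20))
        np.fill_diagonal(S, 0.0)
        return cls("Poisson", S, np.full(20, 0.05))


def discrete_gamma_rates(alpha: float, n_categories: int) -> np.ndarray:
    """Mean rates of ``n_categories`` equal-probability bins of Gamma(alpha, alpha).

    The discretisation of Yang (1994): site rates follow a mean-1 gamma
    distribution with shape ``alpha``; each category rate is the conditional
    mean of its quantile bin, computed from the regularised incomplete gamma
    function so the category means average exactly to 1.
    """
    if alpha <= 0:
        raise ValueError("gamma shape must be > 0")
    if n_categories < 1:
        raise ValueError("need at least one rate category")
    k = n_categories
    edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), a=alpha, scale=1.0 / alpha)
    # E[X ; X in bin] = P(Gamma(alpha+1, alpha) in bin) for a mean-1 gamma
    upper = gammainc(alpha + 1, alpha * edges[1:])
    lower = gammainc(alpha + 1, alpha * edges[:-1])
    rates = k * (upper - lower)
    return rates / rates.mean()


def encode_sequence(seq: str) -> np.ndarray:
    """Residues -> integer codes; gaps/unknowns -> -1 (treated as missing)."""
    return np.array([AA_INDEX.get(c, -1) for c in seq.upper()], dtype=np.int64)


def decode_states(states) -> str:
    return "".join(AMINO_ACIDS[s] if s >= 0 else "-" for s in states)
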