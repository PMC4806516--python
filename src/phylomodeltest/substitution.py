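"""Time-reversible 4x4 rate matrices, transition probabilities, discrete-Gamma rates.

State order is (A, C, G, T); rate order follows
:data:`phylomodeltest.model_space.RATE_POSITIONS`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaincinv, gammainc

from .model_space import k_of, normalize, _check

__all__ = [
    "NUCLEOTIDES",
    "SubstitutionModel",
    "RateMatrix",
    "rate_classes",
    "expand_rates",
    "build_q",
    "transition_probs",
    "gamma_category_rates",
]

NUCLEOTIDES = "ACGT"

#: index of the GT rate position, whose tie class is pinned to 1.0
_GT_POS = 5


class ParameterError(ValueError):
    pass


def rate_classes(model_string: str) -> tuple[list[str], str]:
    """Digit classes of a model string in order of first appearance.

    Returns ``(classes, fixed_class)`` where ``fixed_class`` is the digit
    whose tie class contains the GT position (its rate is pinned to 1.0) and
    ``classes`` lists the remaining digits — the free rate parameters, of
    which a k-model has k-1.
    """
    _check(model_string)
    order: list[str] = []
    for ch in model_string:
        if ch not in order:
            order.append(ch)
    fixed = model_string[_GT_POS]
    return [d for d in order if d != fixed], fixed


def expand_rates(model_string: str, free_rates) -> np.ndarray:
    """Six-vector of exchangeabilities from the free per-class values.

    ``free_rates`` are ordered as in :func:`rate_classes`; the GT class is 1.0.
    """
    free_classes, fixed = rate_classes(model_string)
    free_rates = np.asarray(free_rates, dtype=float)
    if free_rates.shape != (len(free_classes),):
        raise ParameterError(
            f"model {model_string} needs {len(free_classes)} free rates, "
            f"got {free_rates.shape}"
        )
    if np.any(free_rates <= 0):
        raise ParameterError("rates must be strictly positive")
    value = {fixed: 1.0}
    value.update(zip(free_classes, free_rates))
    return np.array([value[ch] for ch in model_string])


@dataclass
class SubstitutionModel:
    """A substitution model instance: string, tied rates, frequencies, Gamma shape."""

    model_string: str
    free_rates: np.ndarray = None  # per free class, order of rate_classes()
    freqs: np.ndarray = None
    alpha: float = 1.0
    freq_mode: str = "empirical"  # empirical | ml_estimated | fixed_equal
    ncat: int = 4

    def __post_init__(self):
        self.model_string = normalize(self.model_string)
        n_free = k_of(self.model_string) - 1
        if self.free_rates is None:
            self.free_rates = np.ones(n_free)
        self.free_rates = np.asarray(self.free_rates, dtype=float)
        if self.free_rates.shape != (n_free,):
            raise ParameterError(
                f"model {self.model_string} needs {n_free} free rates, "
                f"got shape {self.free_rates.shape}"
            )
        if self.freqs is None:
            self.freqs = np.full(4, 0.25)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.shape != (4,) or np.any(self.freqs <= 0):
            raise ParameterError("freqs must be 4 strictly positive values")
        if abs(self.freqs.sum() - 1.0) > 1e-12:
            raise ParameterError("freqs must sum to 1 within 1e-12")
        if not self.alpha > 0:
            raise ParameterError("alpha must be > 0")

    @property
    def rates(self) -> np.ndarray:
        """All six exchangeabilities (AC, AG, AT, CG, CT, GT)."""
        return expand_rates(self.model_string, self.free_rates)

    @property
    def k(self) -> int:
        return k_of(self.model_string)

    def n_free_params(self, n_taxa: int, include_branch_lengths: bool = True) -> int:
        n = (self.k - 1) + 1  # rates + alpha
        if self.freq_mode == "ml_estimated":
            n += 3
        if include_branch_lengths:
            n += 2 * n_taxa - 3
        return n


@dataclass
class RateMatrix:
    """Scaled generator Q with its eigendecomposition for fast P(t).

    Q is normalized to one expected substitution per unit time
    (-sum_i pi_i q_ii = 1).  The decomposition uses the pi-symmetrized form
    diag(sqrt pi) Q diag(1/sqrt pi), which is real symmetric for any
    time-reversible model.
    """

    q: np.ndarray
    freqs: np.ndarray
    eigvals: np.ndarray = field(repr=False, default=None)
    _left: np.ndarray = field(repr=False, default=None)   # D^{-1/2} V
    _right: np.ndarray = field(repr=False, default=None)  # V^T D^{1/2}

    def __post_init__(self):
        if self.eigvals is None:
            sq = np.sqrt(self.freqs)
            b = (sq[:, None] * self.q) / sq[None, :]
            b = 0.5 * (b + b.T)  # symmetrize away rounding noise
            w, v = np.linalg.eigh(b)
            self.eigvals = w
            self._left = v / sq[:, None]
            self._right = v.T * sq[None, :]

    def expm(self, t: float) -> np.ndarray:
        """P(t) = exp(Q t)."""
        return (self._left * np.exp(self.eigvals * t)) @ self._right

    def expm_multi(self, ts: np.ndarray) -> np.ndarray:
        """Stack of P(t) for an array of scaled times; shape (len(ts), 4, 4)."""
        ts = np.asarray(ts, dtype=float)
        e = np.exp(np.multiply.outer(ts, self.eigvals))  # (n, 4)
        return np.einsum("ij,nj,jk->nik", self._left, e, self._right)


def build_q(model: SubstitutionModel) -> RateMatrix:
    """Assemble and scale the reversible generator q_ij = r_ij pi_j."""
    r = model.rates
    pi = model.freqs
    if np.any(r <= 0):
        raise ParameterError("rates must be strictly positive")
    q = np.zeros((4, 4))
    idx = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]  # AC AG AT CG CT GT
    for (i, j), rate in zip(idx, r):
        q[i, j] = rate * pi[j]
        q[j, i] = rate * pi[i]
    np.fill_diagonal(q, -q.sum(axis=1))
    scale = -np.dot(pi, np.diag(q))
    q /= scale
    return RateMatrix(q=q, freqs=pi)


def transition_probs(qm: RateMatrix, t: float, r: float = 1.0) -> np.ndarray:
    """P(t) = exp(Q r t), clipped into [0, 1] against rounding noise."""
    if t < 0 or not np.isfinite(t):
        raise ParameterError(f"branch length must be finite and >= 0, got {t}")
    if r <= 0:
        raise ParameterError("rate multiplier must be > 0")
    p = qm.expm(t * r)
    return np.clip(p, 0.0, 1.0)


def gamma_category_rates(alpha: float, ncat: int = 4) -> np.ndarray:
    """Mean rates of ``ncat`` equal-probability categories of Gamma(alpha, alpha).

    The category rate is the conditional mean of the distribution over its
    quantile interval; rates are renormalized to average exactly 1.
    """
    if not alpha > 0:
        raise ParameterError("alpha must be > 0")
    if ncat < 1:
        raise ParameterError("ncat must be >= 1")
    if ncat == 1:
        return np.ones(1)
    # quantile boundaries of Gamma(shape=alpha, rate=alpha)
    probs = np.arange(1, ncat) / ncat
    cuts = gammaincinv(alpha, probs) / alpha
    # mean over [a, b] of Gamma(alpha, alpha) is the increment of the
    # regularized incomplete gamma with shape alpha+1 (mean of the whole is 1)
    upper = np.concatenate([gammainc(alpha + 1, cuts * alpha), [1.0]])
    lower = np.concatenate([[0.0], gammainc(alpha + 1, cuts * alpha)])
    rates = ncat * (upper - lower)
    return rates / rates.mean()
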