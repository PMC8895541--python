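"""Time-reversible amino-acid substitution models.

A model is a symmetric exchangeability matrix, a stationary frequency
vector pi, and optionally a discrete-gamma distribution of site rates.
The instantaneous rate matrix is Q = S.diag(pi), rescaled so that the mean
rate -sum_i pi_i Q_ii equals 1, i.e. branch lengths are expected
substitutions per site.

Transition probabilities use the symmetric eigendecomposition of
diag(sqrt(pi)) Q diag(1/sqrt(pi)), which is exact and stable for
reversible Q; a generic ``expm`` route is kept as an independent path for
cross-checks.
"""

from __future__ import annotations

from functools import cached_property
from pathlib import Path

import numpy as np
from scipy.linalg import expm
from scipy.stats import gamma as gamma_dist

from .alignment import N_STATES

__all__ = [
    "SubstModel",
    "build_rate_matrix",
    "transition_matrix",
    "discrete_gamma_rates",
    "poisson_model",
    "read_paml_matrix",
]


def build_rate_matrix(exch: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Build the normalized reversible rate matrix Q from S and pi.

    Q_ij = S_ij * pi_j for i != j, diagonal set so rows sum to zero, the
    whole matrix rescaled to mean rate 1 (-sum pi_i Q_ii = 1).
    """
    exch = np.asarray(exch, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    if exch.shape != (N_STATES, N_STATES):
        raise ValueError("exchangeabilities must be 20x20")
    if not np.allclose(exch, exch.T, atol=1e-12):
        raise ValueError("exchangeabilities must be symmetric")
    if np.any(exch < 0):
        raise ValueError("exchangeabilities must be nonnegative")
    if freqs.shape != (N_STATES,) or np.any(freqs <= 0):
        raise ValueError("frequencies must be 20 positive values")
    if not np.isclose(freqs.sum(), 1.0, atol=1e-8):
        raise ValueError("frequencies must sum to 1")
    freqs = freqs / freqs.sum()
    Q = exch * freqs[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mean_rate = -float(freqs @ np.diag(Q))
    if mean_rate <= 0:
        raise ValueError("degenerate model: zero mean rate")
    return Q / mean_rate


def discrete_gamma_rates(shape: float, k: int) -> np.ndarray:
    """Mean-per-quantile discrete gamma rates (k equiprobable categories).

    The gamma has shape alpha and mean 1.  Category means follow from the
    incomplete-gamma identity so that the k rates average exactly 1.
    """
    if k == 1:
        return np.ones(1)
    alpha = float(shape)
    bounds = gamma_dist.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha)
    upper = gamma_dist.cdf(np.concatenate([bounds, [np.inf]]), a=alpha + 1, scale=1.0 / alpha)
    lower = gamma_dist.cdf(np.concatenate([[0.0], bounds]), a=alpha + 1, scale=1.0 / alpha)
    return k * (upper - lower)


class SubstModel:
    """Reversible amino-acid substitution model with optional gamma rates."""

    def __init__(
        self,
        exch: np.ndarray,
        freqs: np.ndarray,
        gamma_shape: float | None = None,
        n_rate_categories: int = 1,
        name: str = "custom",
    ):
        if gamma_shape is not None and gamma_shape <= 0:
            raise ValueError("gamma shape must be positive")
        if n_rate_categories < 1:
            raise ValueError("need at least one rate category")
        if gamma_shape is not None and n_rate_categories == 1:
            n_rate_categories = 4
        self.exch = np.asarray(exch, dtype=float)
        self.freqs = np.asarray(freqs, dtype=float)
        self.freqs = self.freqs / self.freqs.sum()
        self.gamma_shape = gamma_shape
        self.n_rate_categories = n_rate_categories if gamma_shape is not None else 1
        self.name = name
        self.Q = build_rate_matrix(self.exch, self.freqs)

    @cached_property
    def category_rates(self) -> np.ndarray:
        if self.gamma_shape is None:
            return np.ones(1)
        return discrete_gamma_rates(self.gamma_shape, self.n_rate_categories)

    @cached_property
    def _eigen(self):
        # symmetric form B = D Q D^-1 with D = diag(sqrt(pi))
        sq = np.sqrt(self.freqs)
        B = (sq[:, None] * self.Q) / sq[None, :]
        B = 0.5 * (B + B.T)  # symmetrize against round-off
        lam, U = np.linalg.eigh(B)
        left = U.T * sq[None, :]        # U^T D
        right = (1.0 / sq)[:, None] * U  # D^-1 U
        return lam, right, left

    @property
    def eigen(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(eigenvalues, right, left) with P(t) = right @ diag(e^(lam t)) @ left."""
        return self._eigen

    def transition(self, t: float, rate: float = 1.0) -> np.ndarray:
        """P(t) under site-rate multiplier ``rate`` (rows sum to 1)."""
        if t < 0:
            raise ValueError("branch length must be nonnegative")
        if rate <= 0:
            raise ValueError("rate multiplier must be positive")
        lam, right, left = self._eigen
        P = (right * np.exp(lam * t * rate)[None, :]) @ left
        np.clip(P, 0.0, 1.0, out=P)
        return P

    def transitions(self, t: float) -> np.ndarray:
        """Stack of P(t) over all rate categories, shape (ncat, 20, 20)."""
        return np.stack([self.transition(t, r) for r in self.category_rates])

    def with_frequencies(self, freqs: np.ndarray) -> "SubstModel":
        """Same exchangeabilities and rate setup, new stationary frequencies."""
        return SubstModel(
            self.exch, freqs, self.gamma_shape, self.n_rate_categories,
            name=f"{self.name}+Fshift",
        )

    def __repr__(self) -> str:
        g = f", gamma={self.gamma_shape}x{self.n_rate_categories}" if self.gamma_shape else ""
        return f"SubstModel({self.name}{g})"


def transition_matrix(Q: np.ndarray, t: float, rate: float = 1.0) -> np.ndarray:
    """Generic matrix-exponential transition probabilities (cross-check path)."""
    if t < 0:
        raise ValueError("branch length must be nonnegative")
    if rate <= 0:
        raise ValueError("rate multiplier must be positive")
    return expm(np.asarray(Q, dtype=float) * (t * rate))


def poisson_model(
    freqs: np.ndarray | None = None,
    gamma_shape: float | None = None,
    n_rate_categories: int = 4,
) -> SubstModel:
    """Poisson (+F) model: all exchangeabilities equal."""
    exch = np.ones((N_STATES, N_STATES)) - np.eye(N_STATES)
    if freqs is None:
        freqs = np.full(N_STATES, 1.0 / N_STATES)
    return SubstModel(exch, freqs, gamma_shape, n_rate_categories, name="Poisson")


def read_paml_matrix(
    path: str | Path,
    gamma_shape: float | None = None,
    n_rate_categories: int = 4,
    name: str | None = None,
) -> SubstModel:
    """Read a PAML-style model file: 19 lower-triangle rows then frequencies."""
    tokens: list[float] = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            tokens.extend(float(x) for x in line.split())
    need = N_STATES * (N_STATES - 1) // 2 + N_STATES
    if len(tokens) < need:
        raise ValueError(f"model file {path}: expected >= {need} numbers, got {len(tokens)}")
    exch = np.zeros((N_STATES, N_STATES))
    k = 0
    for i in range(1, N_STATES):
        for j in range(i):
            exch[i, j] = exch[j, i] = tokens[k]
            k += 1
    freqs = np.asarray(tokens[k:k + N_STATES])
    return SubstModel(
        exch, freqs, gamma_shape, n_rate_categories,
        name=name or Path(path).stem,
    )


def empirical_synthetic_model(
    gamma_shape: float | None = None, n_rate_categories: int = 4
) -> SubstModel:
    """The packaged synthetic empirical-style matrix (uneven S and pi)."""
    path = Path(__file__).parent / "data" / "empirical_synthetic.paml"
    return read_paml_matrix(path, gamma_shape, n_rate_categories, name="EmpiricalSynthetic")
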