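"""Reversible amino-acid substitution models.

A model is a symmetric matrix of exchangeabilities :math:`s_{ij}`, a vector
of equilibrium frequencies :math:`\\pi`, and (optionally) discrete-gamma
rate heterogeneity.  The rate generator is the standard reversible
construction :math:`q_{ij} = s_{ij}\\pi_j` (:math:`i \\ne j`), with the
diagonal set so rows sum to zero and the whole matrix scaled so that one
unit of branch length equals one expected substitution per site at
equilibrium.

Two empirical matrices are packaged as plain-text data files: LG
(Le & Gascuel 2008) and the Poisson (equal-rates, uniform-frequency)
model.  Both contribute zero free parameters to model comparison; the
gamma shape adds one when present.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .errors import InvalidArgumentError, InvalidModelError

N_STATES = 20
_FREQ_TOL = 1e-12


@dataclass(frozen=True)
class SubstitutionModel:
    """A reversible amino-acid model, optionally with discrete-gamma rates.

    ``gamma_shape=None`` with ``n_categories > 1`` marks the shape as free:
    :func:`paraspec.likelihood.aic_model_selection` will estimate it by
    maximum likelihood.
    """

    name: str
    exchangeabilities: np.ndarray
    frequencies: np.ndarray
    gamma_shape: float | None = None
    n_categories: int = 1
    freqs_estimated: bool = False

    def __post_init__(self):
        s = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.frequencies, dtype=float)
        if s.shape != (N_STATES, N_STATES):
            raise InvalidModelError(f"exchangeabilities must be 20x20, got {s.shape}")
        if not np.allclose(s, s.T, atol=0, rtol=0):
            raise InvalidModelError("exchangeabilities must be symmetric")
        if np.any(s < 0) or np.any(np.diag(s) != 0):
            raise InvalidModelError(
                "exchangeabilities must be >= 0 with a zero diagonal"
            )
        if pi.shape != (N_STATES,):
            raise InvalidModelError("frequencies must have length 20")
        if np.any(pi <= 0):
            raise InvalidModelError("all equilibrium frequencies must be > 0")
        if abs(pi.sum() - 1.0) > _FREQ_TOL:
            raise InvalidModelError(
                f"frequencies sum to {pi.sum():.17g}, not 1 within {_FREQ_TOL}"
            )
        if self.n_categories < 1:
            raise InvalidModelError("n_categories must be >= 1")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise InvalidModelError("gamma shape must be > 0")
        object.__setattr__(self, "exchangeabilities", s)
        object.__setattr__(self, "frequencies", pi)

    @property
    def has_gamma(self) -> bool:
        return self.n_categories > 1

    @property
    def n_free_parameters(self) -> int:
        """Free parameters for information criteria.

        Fixed empirical matrices contribute 0; +1 for a gamma shape (given
        or estimated); +19 when equilibrium frequencies are estimated from
        the data rather than taken from the published matrix.
        """
        k = 0
        if self.has_gamma:
            k += 1
        if self.freqs_estimated:
            k += 19
        return k

    def with_gamma(self, shape: float | None, n_categories: int = 4) -> "SubstitutionModel":
        suffix = "+G" if n_categories > 1 else ""
        base = self.name.split("+")[0]
        return replace(
            self,
            name=base + suffix,
            gamma_shape=shape,
            n_categories=n_categories,
        )

    def category_rates(self) -> np.ndarray:
        """Rates of the discrete-gamma categories (all 1.0 without gamma)."""
        if not self.has_gamma:
            return np.ones(1)
        if self.gamma_shape is None:
            raise InvalidModelError(
                "gamma shape is unset; estimate it first or supply a value"
            )
        return discrete_gamma_rates(self.gamma_shape, self.n_categories)


class RateGenerator:
    """Normalized rate matrix with a cached symmetric eigendecomposition.

    Because the model is reversible the generator is similar to a symmetric
    matrix via ``diag(sqrt(pi))``; transition probabilities are computed
    from the eigendecomposition of that symmetric form, which keeps them
    real and (up to rounding) non-negative.
    """

    def __init__(self, matrix: np.ndarray, frequencies: np.ndarray):
        self.matrix = matrix
        self.frequencies = frequencies
        sqrt_pi = np.sqrt(frequencies)
        sym = matrix * (sqrt_pi[:, None] / sqrt_pi[None, :])
        sym = 0.5 * (sym + sym.T)  # remove rounding asymmetry
        eigvals, eigvecs = np.linalg.eigh(sym)
        self._eigvals = eigvals
        self._left = eigvecs / sqrt_pi[:, None]     # diag(1/sqrt(pi)) @ U
        self._right = (eigvecs * sqrt_pi[:, None]).T  # U.T @ diag(sqrt(pi))

    def transition_matrix(self, t: float) -> np.ndarray:
        """``P(t) = exp(Q t)``: rows sum to 1, entries in [0, 1]."""
        if t < 0:
            raise InvalidArgumentError(f"branch length must be >= 0, got {t}")
        p = (self._left * np.exp(self._eigvals * t)) @ self._right
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=1, keepdims=True)
        return p


def build_generator(model: SubstitutionModel) -> RateGenerator:
    """Construct the normalized reversible generator for ``model``.

    ``q_ij = s_ij * pi_j`` off the diagonal, rows summing to zero, scaled so
    the expected rate at equilibrium is exactly 1.
    """
    s = model.exchangeabilities
    pi = model.frequencies
    q = s * pi[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    mu = -float(pi @ np.diag(q))
    if mu <= 0:
        raise InvalidModelError("degenerate model: zero overall substitution rate")
    q = q / mu
    return RateGenerator(q, pi)


def transition_probabilities(generator, t: float) -> np.ndarray:
    """Transition matrix over branch length ``t``.

    Accepts a :class:`RateGenerator` (fast, eigendecomposition-based) or a
    plain generator matrix (falls back to :func:`scipy.linalg.expm`).
    """
    if t < 0:
        raise InvalidArgumentError(f"branch length must be >= 0, got {t}")
    if isinstance(generator, RateGenerator):
        return generator.transition_matrix(t)
    from scipy.linalg import expm

    return expm(np.asarray(generator, dtype=float) * t)


def discrete_gamma_rates(alpha: float, k: int) -> np.ndarray:
    """Mean rates of ``k`` equal-probability slices of Gamma(alpha, alpha).

    The mean-1 gamma distribution is cut at its ``i/k`` quantiles and each
    category is assigned the conditional mean of its slice, so the category
    rates themselves average exactly 1.
    """
    if alpha <= 0:
        raise InvalidArgumentError(f"gamma shape must be > 0, got {alpha}")
    if k < 1:
        raise InvalidArgumentError(f"number of categories must be >= 1, got {k}")
    if k == 1:
        return np.ones(1)
    # Quantile boundaries of Gamma(shape=alpha, rate=alpha).
    edges = gamma_dist.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha)
    edges = np.concatenate([[0.0], edges, [np.inf]])
    # E[X; a<X<b] for Gamma(alpha, alpha) equals the regularized incomplete
    # gamma with shape alpha+1 evaluated at rate-scaled bounds.
    scaled = edges * alpha
    upper = np.where(np.isinf(scaled), 1.0, gammainc(alpha + 1.0, scaled))
    rates = k * np.diff(upper)
    rates /= rates.mean()
    return rates


def _load_paml_dat(name: str) -> tuple[np.ndarray, np.ndarray]:
    text = resources.files("paraspec.data").joinpath(name).read_text()
    numbers = [float(tok) for tok in text.split()]
    lower = numbers[:190]
    freqs = np.array(numbers[190:210])
    s = np.zeros((N_STATES, N_STATES))
    it = iter(lower)
    for i in range(1, N_STATES):
        for j in range(i):
            s[i, j] = s[j, i] = next(it)
    freqs = freqs / freqs.sum()
    return s, freqs


def lg_model(gamma_shape: float | None = None, n_categories: int = 1) -> SubstitutionModel:
    """The LG empirical model (Le & Gascuel 2008) with optional gamma rates."""
    s, pi = _load_paml_dat("lg.dat")
    name = "LG+G" if n_categories > 1 else "LG"
    return SubstitutionModel(
        name=name,
        exchangeabilities=s,
        frequencies=pi,
        gamma_shape=gamma_shape,
        n_categories=n_categories,
    )


def poisson_model(gamma_shape: float | None = None, n_categories: int = 1) -> SubstitutionModel:
    """Equal exchangeabilities, uniform frequencies."""
    s = np.ones((N_STATES, N_STATES))
    np.fill_diagonal(s, 0.0)
    pi = np.full(N_STATES, 1.0 / N_STATES)
    name = "Poisson+G" if n_categories > 1 else "Poisson"
    return SubstitutionModel(
        name=name,
        exchangeabilities=s,
        frequencies=pi,
        gamma_shape=gamma_shape,
        n_categories=n_categories,
    )


def random_reversible_model(
    seed: int, gamma_shape: float | None = None, n_categories: int = 1
) -> SubstitutionModel:
    """A random valid reversible model; useful for oracle tests."""
    rng = np.random.default_rng(seed)
    s = rng.uniform(0.05, 2.0, size=(N_STATES, N_STATES))
    s = 0.5 * (s + s.T)
    np.fill_diagonal(s, 0.0)
    pi = rng.dirichlet(np.full(N_STATES, 5.0))
    pi = pi / pi.sum()
    return SubstitutionModel(
        name=f"random-{seed}",
        exchangeabilities=s,
        frequencies=pi,
        gamma_shape=gamma_shape,
        n_categories=n_categories,
    )
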