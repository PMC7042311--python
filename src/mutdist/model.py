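"""Closed-form probability model for mutational distances in growing tissues.

A growing tissue (development, cancer) is a branching process of cell
divisions. Each division produces two surviving lineages with probability
``beta`` (a *branching* division) or a single surviving lineage with
probability ``1 - beta`` (a *non-branching* division), and every surviving
daughter acquires a Poisson-distributed number of novel mutations with mean
``mu * L`` (per-base-pair rate ``mu`` times callable genome length ``L``).

The mutational distance ``y`` between two ancestral cells — the number of
mutations private to one of them relative to their common ancestor — then
follows a compound distribution: a coalescent-derived number of branching
divisions ``r``, a negative-binomial number of interleaved non-branching
divisions, and Poisson mutation counts per division. The resulting
distance distribution disentangles ``muL`` and ``beta``: its peak spacing
tracks ``muL`` while its tail weight tracks ``beta``.

All probability mass functions are evaluated with log-gamma arithmetic so
large distances and mutation rates do not overflow naive factorials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "ModelParams",
    "TruncationLimits",
    "DistancePMF",
    "NonGrowingPopulationWarning",
    "prob_mutations_per_division",
    "prob_nonbranching",
    "prob_distance_given_r",
    "coalescent_interval_density",
    "prob_branching_divisions",
    "distance_distribution",
    "beta_from_alpha",
    "alpha_from_beta",
]

#: survival rate at which the population is exactly homeostatic; below it a
#: population shrinks on average (per-daughter death probability > 1/2).
HOMEOSTATIC_BETA = 1.0 / 3.0


class NonGrowingPopulationWarning(UserWarning):
    """Survival rate implies a non-growing (homeostatic or shrinking) population.

    The coalescent approximation used for the branching-division
    distribution assumes exponential growth; evaluations still proceed.
    """


@dataclass(frozen=True)
class ModelParams:
    """Evolutionary parameters of the mutation-accumulation model.

    Parameters
    ----------
    mu
        Mutation rate per base pair per cell division.
    L
        Sequenced (callable) genome length in base pairs.
    beta
        Effective per-cell survival rate per division: the probability
        that both daughter lineages survive, conditioned on
        non-extinction of the observed lineage.
    """

    mu: float
    L: float = 1.0
    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError(f"mu must be >= 0, got {self.mu}")
        if self.L < 1:
            raise ValueError(f"L must be >= 1, got {self.L}")
        if not (0 < self.beta <= 1):
            raise ValueError(f"beta must be in (0, 1], got {self.beta}")
        if self.beta <= HOMEOSTATIC_BETA:
            warnings.warn(
                f"beta = {self.beta} <= 1/3 implies a non-growing population; "
                "the exponential-growth coalescent is an extrapolation here",
                NonGrowingPopulationWarning,
                stacklevel=2,
            )

    @property
    def muL(self) -> float:
        """Genome-wide mutation rate, mutations per genome per division."""
        return self.mu * self.L

    @classmethod
    def from_muL(cls, muL: float, beta: float = 1.0, L: float = 1.0) -> "ModelParams":
        """Build parameters from the per-genome rate ``muL`` directly."""
        return cls(mu=muL / L, L=L, beta=beta)


@dataclass(frozen=True)
class TruncationLimits:
    """Upper cut-offs for the infinite sums of the distance distribution.

    ``r_max`` bounds the number of branching divisions, ``i_max`` the total
    number of divisions. The defaults (30, 30) are conservative for
    observed distance supports of real data; doubling them changes the
    distribution negligibly for beta >= 0.3.
    """

    r_max: int = 30
    i_max: int = 30

    def __post_init__(self) -> None:
        if self.r_max < 1:
            raise ValueError("r_max must be >= 1")
        if self.i_max < self.r_max:
            raise ValueError("i_max must be >= r_max")


DEFAULT_TRUNCATION = TruncationLimits()


@dataclass(frozen=True)
class DistancePMF:
    """Probability mass function of mutational distances on 0..y_max."""

    support: np.ndarray
    probabilities: np.ndarray
    tol: float = 1e-6

    def __post_init__(self) -> None:
        support = np.asarray(self.support, dtype=int)
        probs = np.asarray(self.probabilities, dtype=float)
        if support.shape != probs.shape:
            raise ValueError("support and probabilities must have equal length")
        if np.any(probs < -1e-15) or np.any(probs > 1 + 1e-12):
            raise ValueError("probabilities must lie in [0, 1]")
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "probabilities", np.clip(probs, 0.0, 1.0))

    @property
    def total_mass(self) -> float:
        return float(self.probabilities.sum())

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"y": self.support, "probability": self.probabilities}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "DistancePMF":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(df["y"].to_numpy(), df["probability"].to_numpy())


def _log_poisson_pmf(y: np.ndarray, mean: np.ndarray) -> np.ndarray:
    """log Poisson(y; mean), broadcasting, with mean = 0 handled exactly."""
    y = np.asarray(y, dtype=float)
    mean = np.asarray(mean, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = y * np.log(mean) - mean - gammaln(y + 1.0)
    # mean == 0: point mass at y == 0
    zero = mean == 0
    if np.any(zero):
        out = np.where(zero & (y == 0), 0.0, out)
        out = np.where(zero & (y > 0), -np.inf, out)
    return out


def prob_mutations_per_division(x: int, params: ModelParams) -> float:
    """Probability of acquiring ``x`` novel mutations in one cell division.

    Poisson with mean ``muL`` mutations per genome per division.
    """
    if x < 0 or int(x) != x:
        raise ValueError(f"mutation count x must be a non-negative integer, got {x}")
    return float(np.exp(_log_poisson_pmf(np.asarray(x), np.asarray(params.muL))))


def prob_nonbranching(m: int, r: int, beta: float) -> float:
    """Probability of ``m`` non-branching divisions among ``r`` branching ones.

    Negative binomial: ``C(r+m-1, r-1) beta^r (1-beta)^m``. Each division
    independently branches with probability ``beta``; ``m`` counts the
    single-survivor divisions interleaved before the ``r``-th branching.
    """
    if r < 1:
        raise ValueError(f"r must be >= 1, got {r}")
    if m < 0 or int(m) != m:
        raise ValueError(f"m must be a non-negative integer, got {m}")
    if not (0 < beta <= 1):
        raise ValueError(f"beta must be in (0, 1], got {beta}")
    if beta == 1.0:
        return 1.0 if m == 0 else 0.0
    logc = gammaln(r + m) - gammaln(r) - gammaln(m + 1)
    return float(np.exp(logc + r * np.log(beta) + m * np.log1p(-beta)))


def coalescent_interval_density(dt: float, beta: float) -> float:
    """Density of the interval between successive coalescence events.

    Large-population limit for a deterministically growing population
    ``N(t) = exp(beta t)``, with time measured forward from the founding
    cell in units of cell divisions:

        p(dt) = exp(-beta dt) * exp(-exp(-beta dt) / beta)
    """
    if dt < 0:
        raise ValueError(f"dt must be >= 0, got {dt}")
    if not (0 < beta <= 1):
        raise ValueError(f"beta must be in (0, 1], got {beta}")
    return float(np.exp(-beta * dt) * np.exp(-np.exp(-beta * dt) / beta))


def _branching_pmf_vector(r: np.ndarray, beta: float) -> np.ndarray:
    """Unvalidated vectorised branching-division pmf (discretised coalescent)."""
    r = np.asarray(r, dtype=float)
    upper = np.exp(-np.exp(-beta * (r + 1.0)) / beta)
    lower = np.exp(-np.exp(-beta * r) / beta)
    norm = 1.0 - np.exp(-np.exp(-beta) / beta)
    return (upper - lower) / norm


def prob_branching_divisions(r: int, beta: float) -> float:
    """Probability of ``r`` branching divisions between two ancestral cells.

    Obtained by integrating the coalescent interval density over
    ``[r, r+1]`` and normalising over positive ``r`` (a measured distance
    involves at least one branching division).
    """
    if r < 1:
        raise ValueError(f"r must be >= 1, got {r}")
    if not (0 < beta <= 1):
        raise ValueError(f"beta must be in (0, 1], got {beta}")
    return float(_branching_pmf_vector(np.asarray(r), beta))


def _division_weights(beta: float, trunc: TruncationLimits) -> np.ndarray:
    """Marginal weight of the total division count i, mixing r and m.

    Returns ``w`` of length ``i_max`` with
    ``w[i-1] = sum_r P(r) C(i-1, r-1) beta^r (1-beta)^(i-r)`` so the
    distance pmf becomes a finite Poisson mixture
    ``P(y) = sum_i w[i-1] Poisson(y; i muL)``.
    """
    i = np.arange(1, trunc.i_max + 1)
    r = np.arange(1, trunc.r_max + 1)
    pr = _branching_pmf_vector(r, beta)
    ii, rr = np.meshgrid(i, r, indexing="ij")
    valid = ii >= rr
    logc = np.where(
        valid, gammaln(ii) - gammaln(rr) - gammaln(np.maximum(ii - rr, 0) + 1.0), -np.inf
    )
    # beta = 1: (1-beta)^(i-r) is 1 for i == r, 0 otherwise; 0.0**0 == 1.0
    terms = np.exp(logc) * (beta ** rr) * ((1.0 - beta) ** np.maximum(ii - rr, 0))
    terms = np.where(valid, terms, 0.0)
    return terms @ pr


def _log_distance_pmf(
    y: np.ndarray, muL: float, beta: float, trunc: TruncationLimits = DEFAULT_TRUNCATION
) -> np.ndarray:
    """log P(y) for an array of distances; the workhorse behind inference."""
    y = np.atleast_1d(np.asarray(y, dtype=float))
    w = _division_weights(beta, trunc)
    means = np.arange(1, trunc.i_max + 1) * muL
    with np.errstate(divide="ignore"):
        logw = np.log(w)
    logpois = _log_poisson_pmf(y[:, None], means[None, :])
    return logsumexp(logw[None, :] + logpois, axis=1)


def prob_distance_given_r(
    y: int,
    r: int,
    params: ModelParams,
    trunc: TruncationLimits = DEFAULT_TRUNCATION,
) -> float:
    """Probability of distance ``y`` given ``r`` branching divisions.

    Truncated sum over total divisions ``i = r .. i_max`` of
    ``C(i-1, r-1) beta^r (1-beta)^(i-r) Poisson(y; i muL)``. At
    ``beta = 1`` this collapses exactly to ``Poisson(y; r muL)``.
    """
    if y < 0 or int(y) != y:
        raise ValueError(f"distance y must be a non-negative integer, got {y}")
    if r < 1 or r > trunc.r_max:
        raise ValueError(f"r must be in 1..{trunc.r_max}, got {r}")
    beta, muL = params.beta, params.muL
    if beta == 1.0:
        return float(np.exp(_log_poisson_pmf(np.asarray(y), np.asarray(r * muL))))
    i = np.arange(r, trunc.i_max + 1)
    logc = gammaln(i) - gammaln(r) - gammaln(i - r + 1.0)
    logterm = logc + r * np.log(beta) + (i - r) * np.log1p(-beta)
    logpois = _log_poisson_pmf(np.full_like(i, y, dtype=float), i * muL)
    return float(np.exp(logsumexp(logterm + logpois)))


def distance_distribution(
    params: ModelParams,
    trunc: TruncationLimits = DEFAULT_TRUNCATION,
    y_max: int | None = None,
    tol: float = 1e-6,
) -> DistancePMF:
    """Expected distribution of mutational distances P(y).

    The compound pmf mixes the coalescent branching-division distribution,
    negative-binomial non-branching divisions and Poisson mutation counts.
    If ``y_max`` is omitted, the support is the smallest prefix carrying
    cumulative mass ``>= 1 - tol`` (capped at ``10 * i_max * max(1, muL)``).
    """
    cap = int(np.ceil(10 * trunc.i_max * max(1.0, params.muL)))
    if y_max is None:
        y = np.arange(cap + 1)
        p = np.exp(_log_distance_pmf(y, params.muL, params.beta, trunc))
        cum = np.cumsum(p)
        reached = np.nonzero(cum >= 1.0 - tol)[0]
        last = int(reached[0]) if reached.size else cap
        return DistancePMF(y[: last + 1], p[: last + 1], tol=tol)
    if y_max < 0:
        raise ValueError(f"y_max must be >= 0, got {y_max}")
    y = np.arange(int(y_max) + 1)
    p = np.exp(_log_distance_pmf(y, params.muL, params.beta, trunc))
    return DistancePMF(y, p, tol=tol)


def sample_distances(
    params: ModelParams,
    n: int,
    rng: np.random.Generator,
    trunc: TruncationLimits = DEFAULT_TRUNCATION,
) -> np.ndarray:
    """Draw ``n`` mutational distances by forward simulation of the model.

    Samples ``r`` from the branching-division distribution (truncated at
    ``r_max``), the non-branching count from the negative binomial
    (total divisions capped at ``i_max``), then a Poisson mutation count —
    the generative counterpart of :func:`distance_distribution`.
    """
    r_support = np.arange(1, trunc.r_max + 1)
    pr = _branching_pmf_vector(r_support, params.beta)
    pr = pr / pr.sum()
    r = rng.choice(r_support, size=n, p=pr)
    if params.beta == 1.0:
        m = np.zeros(n, dtype=int)
    else:
        m = rng.negative_binomial(r, params.beta)
    i = np.minimum(r + m, trunc.i_max)
    return rng.poisson(i * params.muL)


def beta_from_alpha(alpha: float) -> float:
    """Effective survival rate from the per-daughter death probability.

    Conditioning a division on non-extinction of both daughter lineages
    gives ``beta = (1-alpha)^2 / (1-alpha^2) = (1-alpha)/(1+alpha)``.
    """
    if not (0 <= alpha < 1):
        raise ValueError(f"alpha must be in [0, 1), got {alpha}")
    return (1.0 - alpha) / (1.0 + alpha)


def alpha_from_beta(beta: float) -> float:
    """Per-daughter death probability from the effective survival rate."""
    if not (0 < beta <= 1):
        raise ValueError(f"beta must be in (0, 1], got {beta}")
    return (1.0 - beta) / (1.0 + beta)
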