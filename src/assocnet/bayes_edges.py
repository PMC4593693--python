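"""Empirical-Bayes beta-binomial inference of edge weights.

Each edge weight θ (the probability that a dyad associates in a sampling
unit) gets a beta prior Beta(a, b) shared across all dyads, updated by
conjugacy with the dyad's counts: observing d co-occurrences in s sampled
units gives the posterior Beta(a + d, b + s − d).

The prior is fitted from the data themselves by type-II maximum likelihood
(empirical Bayes): (a, b) maximize the marginal beta-binomial likelihood of
all dyadic counts, with the unknown edge weights integrated out. Up to
binomial coefficients, which do not depend on (a, b), the log marginal is

    Σ_dyads [ ln B(a + d, b + s − d) − ln B(a, b) ],

with B the beta function. This borrows strength across dyads: the prior
encodes the network-wide distribution of association rates, so sparsely
sampled dyads are shrunk toward it while well-sampled dyads are dominated
by their own counts.

Point estimates are the posterior mode (the most probable edge weight);
uncertainty is the equal-tailed credible interval. Replicate networks drawn
from the per-dyad posteriors propagate edge uncertainty to node-level
metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import betaln
from scipy.stats import beta as beta_dist

from .association import DyadCounts, counts_from_periods
from .estimates import EdgeEstimateSet
from .simnet import SamplingPeriods
from .util import dyads_from_square, square_from_dyads

#: Box bounds on the prior parameters, applied in log space during the fit.
PRIOR_BOUNDS = (1e-3, 1e3)


@dataclass(frozen=True)
class BetaPrior:
    """A fitted (or user-specified) beta prior on edge weights."""

    a: float
    b: float
    fit_log_marginal: float = np.nan
    n_dyads_used: int = 0

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError("prior parameters must be positive")


@dataclass(frozen=True)
class PosteriorNetwork:
    """Per-dyad beta posterior parameters alpha = a + d, beta = b + s − d."""

    alpha: np.ndarray
    beta: np.ndarray
    prior: BetaPrior
    unsampled: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.alpha.shape[0]


def _neg_log_marginal(log_ab: np.ndarray, d: np.ndarray, s: np.ndarray) -> float:
    a, b = np.exp(log_ab)
    return -float(np.sum(betaln(a + d, b + s - d) - betaln(a, b)))


def _moment_start(d: np.ndarray, s: np.ndarray) -> tuple[float, float]:
    """Method-of-moments (a, b) from the per-dyad frequencies, as optimizer start."""
    p = d / s
    m = float(np.mean(p))
    v = float(np.var(p))
    if 0.0 < m < 1.0 and 0.0 < v < m * (1.0 - m):
        common = m * (1.0 - m) / v - 1.0
        a, b = m * common, (1.0 - m) * common
    else:
        a, b = 1.0, 1.0
    lo, hi = PRIOR_BOUNDS
    return float(np.clip(a, lo, hi)), float(np.clip(b, lo, hi))


def fit_empirical_prior(counts: DyadCounts) -> BetaPrior:
    """Fit the shared beta prior by type-II maximum likelihood.

    Maximizes the summed log marginal beta-binomial likelihood over all
    sampled dyads (s > 0; unsampled dyads carry no likelihood and are
    dropped). The optimization runs in (ln a, ln b) space with a
    derivative-free simplex from a method-of-moments start, box-bounded to
    ``PRIOR_BOUNDS``. Degenerate data (every dyad always together, or never
    together) push the maximum to a bound; the fit is then clamped there and
    a warning is emitted.
    """
    mask = dyads_from_square(counts.s) > 0
    d = dyads_from_square(counts.d)[mask].astype(float)
    s = dyads_from_square(counts.s)[mask].astype(float)
    if d.size < 2:
        raise ValueError("prior fitting requires at least 2 sampled dyads")

    lo, hi = PRIOR_BOUNDS
    x0 = np.log(_moment_start(d, s))
    res = optimize.minimize(
        _neg_log_marginal,
        x0,
        args=(d, s),
        method="Nelder-Mead",
        bounds=[(np.log(lo), np.log(hi))] * 2,
        options={"xatol": 1e-10, "fatol": 1e-8, "maxiter": 2000},
    )
    a, b = np.exp(res.x)
    at_bound = np.isclose([a, b], lo, rtol=1e-3).any() or np.isclose(
        [a, b], hi, rtol=1e-3
    ).any()
    if at_bound:
        warnings.warn(
            "empirical-Bayes prior fit attracted to a parameter bound "
            f"(a={a:.4g}, b={b:.4g}); the data may be degenerate",
            RuntimeWarning,
            stacklevel=2,
        )
    return BetaPrior(
        a=float(a), b=float(b), fit_log_marginal=-float(res.fun), n_dyads_used=int(d.size)
    )


def posterior_update(counts: DyadCounts, prior: BetaPrior) -> PosteriorNetwork:
    """Conjugate update: alpha = a + d, beta = b + (s − d) per dyad.

    Unsampled dyads (s=0) keep the bare prior and are flagged in the
    ``unsampled`` mask.
    """
    alpha = prior.a + counts.d.astype(float)
    beta = prior.b + (counts.s - counts.d).astype(float)
    np.fill_diagonal(alpha, 0.0)
    np.fill_diagonal(beta, 0.0)
    return PosteriorNetwork(
        alpha=alpha, beta=beta, prior=prior, unsampled=counts.unsampled
    )


def posterior_point(post: PosteriorNetwork) -> np.ndarray:
    """Posterior mode of every dyad's Beta(alpha, beta).

    The mode is (alpha−1)/(alpha+beta−2) for an interior peak (alpha>1 and
    beta>1), 0 or 1 when the density piles at a boundary, and falls back to
    the posterior mean when both parameters are ≤ 1 (bathtub-shaped density
    with no single peak); the fallback emits a warning.
    """
    a = dyads_from_square(post.alpha)
    b = dyads_from_square(post.beta)
    mode = np.empty_like(a)

    interior = (a > 1) & (b > 1)
    at_zero = (a <= 1) & (b > 1)
    at_one = (b <= 1) & (a > 1)
    bathtub = (a <= 1) & (b <= 1)

    with np.errstate(invalid="ignore"):
        mode[interior] = (a[interior] - 1) / (a[interior] + b[interior] - 2)
    mode[at_zero] = 0.0
    mode[at_one] = 1.0
    if bathtub.any():
        warnings.warn(
            f"{int(bathtub.sum())} dyad posteriors have no interior mode "
            "(alpha<=1 and beta<=1); reporting the posterior mean for those",
            RuntimeWarning,
            stacklevel=2,
        )
        mode[bathtub] = a[bathtub] / (a[bathtub] + b[bathtub])
    return square_from_dyads(mode, post.n_nodes)


def credible_interval(post: PosteriorNetwork, level: float = 0.95) -> EdgeEstimateSet:
    """Equal-tailed credible interval per dyad at the given mass."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    a = dyads_from_square(post.alpha)
    b = dyads_from_square(post.beta)
    tail = (1.0 - level) / 2.0
    lower = beta_dist.ppf(tail, a, b)
    upper = beta_dist.ppf(1.0 - tail, a, b)
    n = post.n_nodes
    return EdgeEstimateSet(
        method="bayes",
        point=posterior_point(post),
        lower=square_from_dyads(lower, n),
        upper=square_from_dyads(upper, n),
        level=level,
        unsampled=post.unsampled,
        metadata={
            "interval": "equal-tailed",
            "prior_a": post.prior.a,
            "prior_b": post.prior.b,
        },
    )


def draw_posterior_networks(
    post: PosteriorNetwork, n_draws: int, seed: int | None = None
) -> np.ndarray:
    """Draw replicate weight matrices from the per-dyad posteriors.

    Returns an (n_draws, N, N) array of symmetric zero-diagonal matrices.
    Each dyad (row-major i<j order) is drawn independently from its
    Beta(alpha, beta); reproducible for a fixed seed.
    """
    if n_draws < 1:
        raise ValueError(f"n_draws must be >= 1, got {n_draws}")
    rng = np.random.default_rng(seed)
    a = dyads_from_square(post.alpha)
    b = dyads_from_square(post.beta)
    draws = rng.beta(a[None, :], b[None, :], size=(n_draws, a.size))
    return np.stack([square_from_dyads(row, post.n_nodes) for row in draws])


def split_periods(
    obs: SamplingPeriods, fraction: float = 0.5
) -> tuple[SamplingPeriods, SamplingPeriods]:
    """Split sampling periods into a prior-fitting subset and a hold-out.

    Supports the strictly Bayesian variant in which the prior is estimated
    from an initial fraction of the observations and the posterior is
    updated only with the remainder. The split is by observation order
    (first ``ceil(fraction * S)`` periods fit the prior). Off by default in
    all high-level drivers; empirical Bayes on all data is the standard
    route.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    s = obs.n_periods
    k = int(np.ceil(fraction * s))
    if k == 0 or k == s:
        raise ValueError("split leaves one part empty; adjust fraction")
    return obs.subset(np.arange(k)), obs.subset(np.arange(k, s))


def estimate_bayes(
    counts: DyadCounts,
    level: float = 0.95,
    prior: BetaPrior | None = None,
) -> EdgeEstimateSet:
    """Convenience driver: fit prior (unless given), update, and interval."""
    if prior is None:
        prior = fit_empirical_prior(counts)
    post = posterior_update(counts, prior)
    return credible_interval(post, level=level)


def estimate_bayes_from_periods(
    obs: SamplingPeriods, level: float = 0.95, prior: BetaPrior | None = None
) -> EdgeEstimateSet:
    return estimate_bayes(counts_from_periods(obs), level=level, prior=prior)
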