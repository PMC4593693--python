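"""Frequentist comparators: bootstrapped SRI and Clopper–Pearson intervals.

The bootstrap (b-SRI) resamples whole sampling units — complete sampling
periods, or complete observed groups for gambit-of-the-group data — with
replacement, recomputing the SRI network for each resample, and reads the
interval off the percentile quantiles of the replicate edge values.
Resampling whole units keeps each snapshot of the network together, which is
what makes the procedure a valid comparator; resampling individual dyad
records would break the joint structure of an observation.

With a single sampling unit every resample is identical and every bootstrap
interval has width exactly zero — the known degenerate limit of the method.

The Clopper–Pearson interval is the exact small-sample confidence interval
on a binomial proportion, computed per dyad from (d, s) via beta quantiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import beta as beta_dist

from .association import (
    DyadCounts,
    GroupByIndividual,
    counts_from_gbi,
    counts_from_periods,
    sri,
)
from .estimates import EdgeEstimateSet
from .simnet import SamplingPeriods
from .util import dyads_from_square, square_from_dyads

#: Quantile interpolation rule for percentile intervals, recorded in metadata.
QUANTILE_RULE = "linear"


def _units_and_counts(obs):
    """Number of resampling units and a counts-from-index function."""
    if isinstance(obs, SamplingPeriods):
        return obs.n_periods, lambda idx: counts_from_periods(obs.subset(idx))
    if isinstance(obs, GroupByIndividual):
        def from_idx(idx):
            sub = GroupByIndividual(
                matrix=obs.matrix[np.asarray(idx)], individual_ids=obs.individual_ids
            )
            return counts_from_gbi(sub)

        return obs.n_groups, from_idx
    raise TypeError(f"unsupported observation container: {type(obs).__name__}")


@dataclass(frozen=True)
class BootstrapEnsemble:
    """Replicate SRI networks from resampled sampling units."""

    networks: np.ndarray  # (n_boot, N, N)
    observed: np.ndarray  # SRI on the original data
    unsampled: np.ndarray
    seed: int | None = None

    @property
    def n_boot(self) -> int:
        return self.networks.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.observed.shape[0]


def bootstrap_networks(
    obs: SamplingPeriods | GroupByIndividual,
    n_boot: int = 100,
    seed: int | None = None,
) -> BootstrapEnsemble:
    """Resample sampling units with replacement and recompute SRI networks.

    Each of the ``n_boot`` replicates draws S units uniformly with
    replacement from the S observed units and rebuilds the full SRI weight
    matrix. Reproducible for a fixed seed.
    """
    if n_boot < 1:
        raise ValueError(f"n_boot must be >= 1, got {n_boot}")
    n_units, counts_from_idx = _units_and_counts(obs)
    if n_units < 1:
        raise ValueError("at least one sampling unit is required")

    rng = np.random.default_rng(seed)
    nets = []
    for _ in range(n_boot):
        idx = rng.integers(0, n_units, size=n_units)
        nets.append(sri(counts_from_idx(idx)))
    observed_counts = counts_from_idx(np.arange(n_units))
    return BootstrapEnsemble(
        networks=np.stack(nets),
        observed=sri(observed_counts),
        unsampled=observed_counts.unsampled,
        seed=seed,
    )


def bootstrap_edge_interval(
    ens: BootstrapEnsemble, level: float = 0.95
) -> EdgeEstimateSet:
    """Percentile interval per dyad over the bootstrap replicate SRI values.

    The point estimate is the SRI on the original (unresampled) data; the
    bounds are the (1−level)/2 and (1+level)/2 quantiles of the replicate
    values, with linear interpolation between order statistics.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    tail = (1.0 - level) / 2.0
    lower, upper = np.quantile(
        ens.networks, [tail, 1.0 - tail], axis=0, method=QUANTILE_RULE
    )
    np.fill_diagonal(lower, 0.0)
    np.fill_diagonal(upper, 0.0)
    return EdgeEstimateSet(
        method="sri_bootstrap",
        point=ens.observed,
        lower=lower,
        upper=upper,
        level=level,
        unsampled=ens.unsampled,
        metadata={"n_boot": ens.n_boot, "quantile_rule": QUANTILE_RULE},
    )


def clopper_pearson_interval(
    counts: DyadCounts, level: float = 0.95
) -> EdgeEstimateSet:
    """Exact binomial (Clopper–Pearson) interval per dyad from (d, s).

    lower = BetaQuantile((1−level)/2; d, s−d+1), 0 when d = 0;
    upper = BetaQuantile((1+level)/2; d+1, s−d), 1 when d = s.
    Unsampled dyads (s=0) get the uninformative interval (0, 1).
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    d = dyads_from_square(counts.d).astype(float)
    s = dyads_from_square(counts.s).astype(float)
    tail = (1.0 - level) / 2.0

    lower = np.zeros_like(d)
    upper = np.ones_like(d)
    sampled = s > 0
    at_lo = sampled & (d > 0)
    at_hi = sampled & (d < s)
    lower[at_lo] = beta_dist.ppf(tail, d[at_lo], s[at_lo] - d[at_lo] + 1)
    upper[at_hi] = beta_dist.ppf(1.0 - tail, d[at_hi] + 1, s[at_hi] - d[at_hi])

    point = np.zeros_like(d)
    np.divide(d, s, out=point, where=sampled)
    n = counts.n_nodes
    return EdgeEstimateSet(
        method="clopper_pearson",
        point=square_from_dyads(point, n),
        lower=square_from_dyads(lower, n),
        upper=square_from_dyads(upper, n),
        level=level,
        unsampled=counts.unsampled,
        metadata={},
    )
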