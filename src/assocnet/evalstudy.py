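"""Evaluation framework: accuracy, interval reliability, and stability.

Given a ground truth, inferred networks are scored three ways:

* absolute error — mean |estimate − truth| over dyads;
* relative accuracy — Spearman rank correlation between estimated and true
  values (in social-network studies the ordering of association strengths
  usually matters more than their absolute values);
* interval reliability — the false-positive rate (truth strictly below the
  interval: the edge was overestimated) and false-negative rate (truth
  strictly above the interval: the edge was underestimated). Calibrated 95%
  intervals put each tail near 2.5%.

`run_simulation_study` drives the full factorial evaluation over network
types, sampling efforts and estimation methods on simulated ground truth.
`subsample_stability` addresses the field situation where no ground truth
exists: re-estimate the network from growing subsets of the observed data
and watch whether the estimates (and their intervals) stabilize by the time
all data are used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from . import bayes_edges, freq_edges, netmetrics
from .association import (
    DyadCounts,
    GroupByIndividual,
    counts_from_gbi,
    counts_from_periods,
    sri,
)
from .estimates import EdgeEstimateSet
from .netmetrics import MetricDistribution
from .simnet import GeneratorConfig, SamplingPeriods, generate_true_network, sample_observations
from .util import dyads_from_square

EDGE_METHODS = ("bayes", "sri_bootstrap", "clopper_pearson")


def mean_absolute_error(estimate: np.ndarray, truth: np.ndarray) -> float:
    """Mean |estimate − truth| over unordered dyads (i < j)."""
    estimate = np.asarray(estimate, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if estimate.shape != truth.shape:
        raise ValueError("estimate and truth must have the same shape")
    return float(np.mean(np.abs(dyads_from_square(estimate) - dyads_from_square(truth))))


def rank_correlation(estimate: np.ndarray, truth: np.ndarray) -> float:
    """Spearman rank correlation (average ranks for ties).

    Returns NaN with a warning when either vector is constant, where the
    correlation is undefined.
    """
    estimate = np.ravel(estimate)
    truth = np.ravel(truth)
    if estimate.shape != truth.shape:
        raise ValueError("inputs must have the same length")
    if estimate.size < 3:
        raise ValueError("rank correlation needs at least 3 values")
    if np.ptp(estimate) == 0 or np.ptp(truth) == 0:
        warnings.warn(
            "rank correlation undefined for constant input; returning NaN",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("nan")
    rho, _ = spearmanr(estimate, truth)
    return float(rho)


def interval_coverage(
    est: EdgeEstimateSet | MetricDistribution, truth: np.ndarray
) -> tuple[float, float]:
    """False-positive and false-negative rates of an interval set.

    A false positive is a quantity whose true value falls strictly below the
    interval's lower bound (the interval overestimates it); a false negative
    falls strictly above the upper bound. Edge intervals are compared over
    dyads (i < j), node-metric intervals over nodes.
    """
    if isinstance(est, EdgeEstimateSet):
        lower = dyads_from_square(est.lower)
        upper = dyads_from_square(est.upper)
        truth = dyads_from_square(np.asarray(truth))
    else:
        lower, upper = est.lower, est.upper
        truth = np.ravel(truth)
    if truth.shape != lower.shape:
        raise ValueError("truth is not aligned with the interval set")
    fp = float(np.mean(truth < lower))
    fn = float(np.mean(truth > upper))
    return fp, fn


def estimate_edges(
    obs_or_counts,
    method: str,
    level: float = 0.95,
    n_boot: int = 100,
    seed: int | None = None,
    prior: bayes_edges.BetaPrior | None = None,
) -> EdgeEstimateSet:
    """Dispatch to one of the three edge-interval methods.

    Accepts SamplingPeriods, GroupByIndividual or precomputed DyadCounts
    (counts are not enough for the bootstrap, which needs the sampling
    units themselves).
    """
    if method not in EDGE_METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {EDGE_METHODS}")
    if method == "sri_bootstrap":
        if isinstance(obs_or_counts, DyadCounts):
            raise TypeError("the bootstrap needs sampling units, not DyadCounts")
        ens = freq_edges.bootstrap_networks(obs_or_counts, n_boot=n_boot, seed=seed)
        return freq_edges.bootstrap_edge_interval(ens, level=level)

    counts = _as_counts(obs_or_counts)
    if method == "bayes":
        return bayes_edges.estimate_bayes(counts, level=level, prior=prior)
    return freq_edges.clopper_pearson_interval(counts, level=level)


def _as_counts(obs_or_counts) -> DyadCounts:
    if isinstance(obs_or_counts, DyadCounts):
        return obs_or_counts
    if isinstance(obs_or_counts, SamplingPeriods):
        return counts_from_periods(obs_or_counts)
    if isinstance(obs_or_counts, GroupByIndividual):
        return counts_from_gbi(obs_or_counts)
    raise TypeError(f"unsupported input: {type(obs_or_counts).__name__}")


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of the simulation study.

    The factorial crosses network sizes × clique structure × sampling
    efforts × methods, with ``n_networks`` replicate ground-truth networks
    per cell. ``node_metrics`` adds node-level evaluation via replicate
    ensembles (posterior draws for the Bayesian method, resampled networks
    for the bootstrap; the Clopper–Pearson method is edge-only).
    """

    n_nodes: tuple[int, ...] = (15,)
    cliques: tuple[bool, ...] = (True,)
    s_grid: tuple[int, ...] = (10, 20, 50)
    n_networks: int = 100
    methods: tuple[str, ...] = ("bayes", "sri_bootstrap", "clopper_pearson")
    node_metrics: tuple[str, ...] = ()
    n_boot: int = 100
    n_posterior_draws: int = 100
    level: float = 0.95
    seed: int = 0
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)

    def __post_init__(self) -> None:
        if any(m not in EDGE_METHODS for m in self.methods):
            raise ValueError(f"methods must be among {EDGE_METHODS}")
        if any(m not in netmetrics.METRICS for m in self.node_metrics):
            raise ValueError(f"node_metrics must be among {sorted(netmetrics.METRICS)}")
        if tuple(self.s_grid) != tuple(sorted(set(self.s_grid))):
            raise ValueError("s_grid must be strictly increasing")


def run_simulation_study(config: StudyConfig) -> pd.DataFrame:
    """Run the full evaluation study; one row per replicate × cell × level.

    For each replicate network the maximum sampling effort is simulated once
    and each grid value S uses the first S periods (periods are i.i.d., so a
    prefix is a valid sample of that size). Columns: network descriptors,
    ``s``, ``method``, ``level`` ("edge" or a node-metric name),
    ``mean_error``, ``rank_correlation``, ``fp_rate``, ``fn_rate``.
    Fully seeded and reproducible.
    """
    rng = np.random.default_rng(config.seed)
    rows: list[dict] = []
    s_max = max(config.s_grid)

    for n in config.n_nodes:
        for cliq in config.cliques:
            for rep in range(config.n_networks):
                g = GeneratorConfig(
                    n_nodes=n,
                    cliques=cliq,
                    n_cliques=config.generator.n_cliques,
                    poisson_rate=config.generator.poisson_rate,
                    gregariousness_offset=config.generator.gregariousness_offset,
                    p_within=config.generator.p_within,
                    p_between=config.generator.p_between,
                    p_nocliques=config.generator.p_nocliques,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                net = generate_true_network(g)
                obs = sample_observations(net, s_max, seed=int(rng.integers(0, 2**31 - 1)))
                for s in config.s_grid:
                    sub = obs.subset(np.arange(s))
                    for method in config.methods:
                        rows.extend(
                            _evaluate_cell(
                                net, sub, method, config, rep, rng, n, cliq, s
                            )
                        )
    return pd.DataFrame(rows)


def _evaluate_cell(net, sub, method, config, rep, rng, n, cliq, s) -> list[dict]:
    base = {
        "n_nodes": n,
        "cliques": cliq,
        "replicate": rep,
        "s": s,
        "method": method,
    }
    rows = []
    seed = int(rng.integers(0, 2**31 - 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        est = estimate_edges(
            sub, method, level=config.level, n_boot=config.n_boot, seed=seed
        )
        fp, fn = interval_coverage(est, net.weights)
        rows.append(
            base
            | {
                "level": "edge",
                "mean_error": mean_absolute_error(est.point, net.weights),
                "rank_correlation": rank_correlation(
                    dyads_from_square(est.point), dyads_from_square(net.weights)
                ),
                "fp_rate": fp,
                "fn_rate": fn,
            }
        )
        if config.node_metrics and method != "clopper_pearson":
            replicates = _replicate_networks(sub, method, config, rng)
            for metric in config.node_metrics:
                md = netmetrics.metric_uncertainty(
                    replicates, metric, level=config.level, point_network=est.point
                )
                truth_vals = netmetrics.METRICS[metric](net.weights)
                nfp = float(np.mean(truth_vals < md.lower))
                nfn = float(np.mean(truth_vals > md.upper))
                rows.append(
                    base
                    | {
                        "level": metric,
                        "mean_error": float(np.mean(np.abs(md.point - truth_vals))),
                        "rank_correlation": rank_correlation(md.point, truth_vals),
                        "fp_rate": nfp,
                        "fn_rate": nfn,
                    }
                )
    return rows


def _replicate_networks(sub, method, config, rng) -> np.ndarray:
    seed = int(rng.integers(0, 2**31 - 1))
    if method == "bayes":
        counts = counts_from_periods(sub)
        prior = bayes_edges.fit_empirical_prior(counts)
        post = bayes_edges.posterior_update(counts, prior)
        return bayes_edges.draw_posterior_networks(
            post, config.n_posterior_draws, seed=seed
        )
    ens = freq_edges.bootstrap_networks(sub, n_boot=config.n_posterior_draws, seed=seed)
    return ens.networks


def summarize_study(results: pd.DataFrame) -> pd.DataFrame:
    """Median and 95% range over replicate networks for each study cell."""
    keys = ["n_nodes", "cliques", "s", "method", "level"]
    metrics = ["mean_error", "rank_correlation", "fp_rate", "fn_rate"]

    def agg(g: pd.DataFrame) -> pd.Series:
        out = {}
        for m in metrics:
            v = g[m].to_numpy(dtype=float)
            v = v[np.isfinite(v)]
            if v.size == 0:
                out[f"{m}_median"] = np.nan
                out[f"{m}_q2.5"] = np.nan
                out[f"{m}_q97.5"] = np.nan
            else:
                out[f"{m}_median"] = float(np.median(v))
                out[f"{m}_q2.5"] = float(np.quantile(v, 0.025))
                out[f"{m}_q97.5"] = float(np.quantile(v, 0.975))
        return pd.Series(out)

    return results.groupby(keys, sort=True).apply(agg, include_groups=False).reset_index()


@dataclass(frozen=True)
class ReliabilityCurve:
    """Estimates and interval bounds as a function of sampling effort.

    ``grid`` holds the increasing sampling-effort values; edge arrays have
    shape (len(grid), n_dyads) in row-major i<j dyad order; mean-degree
    arrays are per grid point (NaN bounds where a method defines no
    network-level ensemble). ``stabilized`` reports whether the tracked
    mean degree has settled between the final two grid points — a reporting
    heuristic, not a test.
    """

    method: str
    grid: np.ndarray
    edge_point: np.ndarray
    edge_lower: np.ndarray
    edge_upper: np.ndarray
    mean_degree_point: np.ndarray
    mean_degree_lower: np.ndarray
    mean_degree_upper: np.ndarray
    level: float
    mode: str
    stabilized: bool | None
    stabilization_tol: float


def subsample_stability(
    obs: SamplingPeriods | GroupByIndividual,
    method: str = "bayes",
    grid_step: int = 20,
    mode: str = "cumulative",
    level: float = 0.95,
    n_replicates: int = 100,
    seed: int | None = None,
    stabilization_tol: float = 0.05,
) -> ReliabilityCurve:
    """Re-estimate the network from growing subsets of the observed data.

    For each sampling effort on the grid (grid_step, 2·grid_step, ..., total)
    the first S sampling units in observation order are used
    (``mode="cumulative"``, the default) or a seeded random subset without
    replacement (``mode="random"``). Edge point estimates and interval
    bounds are recorded per dyad, together with the mean weighted degree and
    its ensemble interval (posterior draws for the Bayesian method,
    bootstrap replicates for b-SRI; none for Clopper–Pearson).

    The stabilization diagnostic is true when the last two grid points'
    mean-degree intervals mutually overlap and the point estimates differ by
    less than ``stabilization_tol`` (relative).
    """
    if grid_step < 1:
        raise ValueError("grid_step must be >= 1")
    if mode not in ("cumulative", "random"):
        raise ValueError("mode must be 'cumulative' or 'random'")
    n_units, _ = freq_edges._units_and_counts(obs)
    grid = list(range(grid_step, n_units + 1, grid_step))
    if not grid or grid[-1] != n_units:
        grid.append(n_units)
    if len(grid) == 1:
        warnings.warn(
            "grid step exceeds the number of sampling units; "
            "reliability curve has a single point",
            RuntimeWarning,
            stacklevel=2,
        )

    rng = np.random.default_rng(seed)
    tail = (1.0 - level) / 2.0
    ep, el, eu, mp, ml, mu = [], [], [], [], [], []
    for s in grid:
        if mode == "cumulative":
            idx = np.arange(s)
        else:
            idx = rng.choice(n_units, size=s, replace=False)
        sub = _take_units(obs, idx)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            est = estimate_edges(
                sub, method, level=level, n_boot=n_replicates,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            ep.append(dyads_from_square(est.point))
            el.append(dyads_from_square(est.lower))
            eu.append(dyads_from_square(est.upper))
            mp.append(float(np.mean(netmetrics.weighted_degree(est.point))))
            if method == "clopper_pearson":
                ml.append(np.nan)
                mu.append(np.nan)
            else:
                cfg = StudyConfig(n_posterior_draws=n_replicates, n_boot=n_replicates)
                reps = _replicate_networks_any(sub, method, cfg, rng)
                mean_deg = np.array(
                    [float(np.mean(netmetrics.weighted_degree(r))) for r in reps]
                )
                ml.append(float(np.quantile(mean_deg, tail)))
                mu.append(float(np.quantile(mean_deg, 1.0 - tail)))

    stabilized: bool | None = None
    if len(grid) >= 2 and np.isfinite(ml[-1]) and np.isfinite(mu[-1]):
        overlap = (ml[-1] <= mu[-2]) and (ml[-2] <= mu[-1])
        denom = max(abs(mp[-1]), 1e-12)
        stabilized = bool(overlap and abs(mp[-1] - mp[-2]) / denom < stabilization_tol)

    return ReliabilityCurve(
        method=method,
        grid=np.asarray(grid),
        edge_point=np.stack(ep),
        edge_lower=np.stack(el),
        edge_upper=np.stack(eu),
        mean_degree_point=np.asarray(mp),
        mean_degree_lower=np.asarray(ml),
        mean_degree_upper=np.asarray(mu),
        level=level,
        mode=mode,
        stabilized=stabilized,
        stabilization_tol=stabilization_tol,
    )


def _take_units(obs, idx):
    if isinstance(obs, SamplingPeriods):
        return obs.subset(idx)
    return GroupByIndividual(
        matrix=obs.matrix[np.asarray(idx)], individual_ids=obs.individual_ids
    )


def _replicate_networks_any(sub, method, config, rng) -> np.ndarray:
    if isinstance(sub, SamplingPeriods):
        return _replicate_networks(sub, method, config, rng)
    # GBI input
    seed = int(rng.integers(0, 2**31 - 1))
    if method == "bayes":
        counts = counts_from_gbi(sub)
        prior = bayes_edges.fit_empirical_prior(counts)
        post = bayes_edges.posterior_update(counts, prior)
        return bayes_edges.draw_posterior_networks(
            post, config.n_posterior_draws, seed=seed
        )
    ens = freq_edges.bootstrap_networks(sub, n_boot=config.n_posterior_draws, seed=seed)
    return ens.networks
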