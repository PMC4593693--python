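"""Weighted node-level metrics and their uncertainty from replicate networks.

Three standard node metrics for weighted association networks:

* weighted degree (strength) — the sum of a node's edge weights;
* weighted eigenvector centrality — the leading eigenvector of the weight
  matrix, rescaled so its maximum component is 1;
* weighted betweenness — shortest-path betweenness on edge lengths 1/weight
  (strong associations are short), unnormalized pair counts.

Uncertainty is propagated by evaluating a metric on an ensemble of replicate
networks (posterior draws, or bootstrap resamples) and taking per-node
percentile intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .util import check_symmetric_zero_diagonal


def weighted_degree(weights: np.ndarray) -> np.ndarray:
    """Node strength: the sum of each node's edge weights."""
    check_symmetric_zero_diagonal(weights, "weights")
    return weights.sum(axis=1)


def eigenvector_centrality(weights: np.ndarray) -> np.ndarray:
    """Leading-eigenvector centrality, rescaled so the maximum is 1.

    By Perron–Frobenius the leading eigenvector of a connected non-negative
    matrix can be taken entrywise non-negative; the sign is fixed
    accordingly. For a disconnected network the centrality is computed on
    the largest connected component and set to 0 elsewhere, with a warning.
    """
    check_symmetric_zero_diagonal(weights, "weights")
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    if not np.any(weights > 0):
        raise ValueError("eigenvector centrality is undefined for an empty network")

    n_comp, labels = connected_components(csr_matrix(weights), directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        keep = labels == np.argmax(sizes)
        warnings.warn(
            f"network has {n_comp} components; centrality computed on the "
            f"largest ({keep.sum()} nodes), 0 elsewhere",
            RuntimeWarning,
            stacklevel=2,
        )
    else:
        keep = np.ones(weights.shape[0], dtype=bool)

    sub = weights[np.ix_(keep, keep)]
    vals, vecs = np.linalg.eigh(sub)
    lead = vecs[:, -1]
    # Perron vector: make non-negative, then rescale to max 1
    if lead.sum() < 0:
        lead = -lead
    lead = np.clip(lead, 0.0, None)
    out = np.zeros(weights.shape[0])
    out[keep] = lead / lead.max()
    return out


def weighted_betweenness(weights: np.ndarray) -> np.ndarray:
    """Shortest-path betweenness with edge lengths 1/weight.

    Returns raw (unnormalized) counts of unordered source–target pairs whose
    shortest paths pass through each node, with ties split fractionally.
    Zero-weight edges are absent; disconnected pairs contribute nothing.
    """
    check_symmetric_zero_diagonal(weights, "weights")
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    g = nx.Graph()
    g.add_nodes_from(range(weights.shape[0]))
    iu, ju = np.triu_indices(weights.shape[0], k=1)
    for i, j in zip(iu, ju):
        w = weights[i, j]
        if w > 0:
            g.add_edge(int(i), int(j), length=1.0 / w)
    bc = nx.betweenness_centrality(g, weight="length", normalized=False)
    return np.array([bc[i] for i in range(weights.shape[0])])


METRICS = {
    "degree": weighted_degree,
    "eigenvector": eigenvector_centrality,
    "betweenness": weighted_betweenness,
}


@dataclass(frozen=True)
class MetricDistribution:
    """Per-node metric values over replicate networks with interval bounds."""

    metric: str
    values: np.ndarray  # (n_replicates, N)
    point: np.ndarray  # (N,)
    lower: np.ndarray
    upper: np.ndarray
    level: float = 0.95

    @property
    def n_replicates(self) -> int:
        return self.values.shape[0]


def metric_uncertainty(
    replicates: np.ndarray,
    metric: str,
    level: float = 0.95,
    point_network: np.ndarray | None = None,
) -> MetricDistribution:
    """Evaluate a node metric on replicate networks and band it.

    ``replicates`` is an (R, N, N) stack (R >= 2) of symmetric weight
    matrices, e.g. posterior draws or bootstrap resamples. The metric is
    evaluated per replicate; per-node bounds are the equal-tailed percentile
    interval at ``level``. The ``point`` value is the metric on
    ``point_network`` when given, otherwise on the elementwise mean of the
    replicates.
    """
    if metric not in METRICS:
        raise KeyError(f"unknown metric {metric!r}; choose from {sorted(METRICS)}")
    replicates = np.asarray(replicates)
    if replicates.ndim != 3 or replicates.shape[0] < 2:
        raise ValueError("need an (R, N, N) stack with R >= 2 replicates")
    fn = METRICS[metric]
    values = np.stack([fn(net) for net in replicates])
    tail = (1.0 - level) / 2.0
    lower, upper = np.quantile(values, [tail, 1.0 - tail], axis=0)
    if point_network is None:
        point_network = replicates.mean(axis=0)
    return MetricDistribution(
        metric=metric,
        values=values,
        point=fn(point_network),
        lower=lower,
        upper=upper,
        level=level,
    )
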