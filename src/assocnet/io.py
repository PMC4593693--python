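"""CSV/JSON readers and writers for networks, observations and estimates.

All on-disk artifacts are plain text: adjacency matrices as CSV with node
IDs in the header row and first column, observations in long format
(period, node_i, node_j, together), and run metadata as JSON sidecars.
"""

from __future__ import annotations

import json
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd

from .bayes_edges import BetaPrior, PosteriorNetwork
from .estimates import EdgeEstimateSet
from .netmetrics import MetricDistribution
from .simnet import SamplingPeriods, TrueNetwork
from .util import square_from_dyads


def _ids(n: int, ids=None) -> list[str]:
    return [str(i) for i in ids] if ids is not None else [str(i) for i in range(n)]


def write_adjacency_csv(matrix: np.ndarray, path, node_ids=None) -> None:
    ids = _ids(matrix.shape[0], node_ids)
    pd.DataFrame(matrix, index=ids, columns=ids).to_csv(path)


def read_adjacency_csv(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


def write_true_network(net: TrueNetwork, out_dir, node_ids=None) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ids = _ids(net.n_nodes, node_ids)
    write_adjacency_csv(net.weights, out / "true_weights.csv", ids)
    nodes = pd.DataFrame({"node_id": ids, "gregariousness": net.gregariousness})
    if net.clique_id is not None:
        nodes["clique_id"] = net.clique_id
    nodes.to_csv(out / "true_nodes.csv", index=False)


def write_periods_long_csv(obs: SamplingPeriods, path, node_ids=None) -> None:
    """Long format: one row per (period, dyad) with the together flag."""
    ids = _ids(obs.n_nodes, node_ids)
    iu, ju = np.triu_indices(obs.n_nodes, k=1)
    rows = {
        "period": np.repeat(np.arange(obs.n_periods), iu.size),
        "node_i": np.tile([ids[i] for i in iu], obs.n_periods),
        "node_j": np.tile([ids[j] for j in ju], obs.n_periods),
        "together": obs.together.ravel(),
    }
    pd.DataFrame(rows).to_csv(path, index=False)


def read_periods_long_csv(path) -> tuple[SamplingPeriods, list[str]]:
    df = pd.read_csv(path, dtype={"node_i": str, "node_j": str})
    ids = sorted(set(df["node_i"]).union(df["node_j"]))
    index = {v: k for k, v in enumerate(ids)}
    n = len(ids)
    periods = sorted(df["period"].unique())
    n_dyads = n * (n - 1) // 2
    iu, ju = np.triu_indices(n, k=1)
    dyad_pos = {(int(i), int(j)): k for k, (i, j) in enumerate(zip(iu, ju))}
    together = np.zeros((len(periods), n_dyads), dtype=np.uint8)
    period_pos = {p: k for k, p in enumerate(periods)}
    for p, a, b, t in zip(df["period"], df["node_i"], df["node_j"], df["together"]):
        i, j = sorted((index[a], index[b]))
        together[period_pos[p], dyad_pos[(i, j)]] = int(t)
    return SamplingPeriods(n_nodes=n, together=together), ids


def write_periods_stacked_csv(obs: SamplingPeriods, path) -> None:
    """Stacked binary matrix: S blocks of N rows, one N×N matrix per period."""
    mats = obs.as_matrices()
    stacked = mats.reshape(-1, obs.n_nodes)
    np.savetxt(path, stacked, fmt="%d", delimiter=",")


def write_edge_estimates(est: EdgeEstimateSet, out_dir, node_ids=None) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ids = _ids(est.n_nodes, node_ids)
    write_adjacency_csv(est.point, out / f"{est.method}_point.csv", ids)
    write_adjacency_csv(est.lower, out / f"{est.method}_lower.csv", ids)
    write_adjacency_csv(est.upper, out / f"{est.method}_upper.csv", ids)
    if est.unsampled is not None:
        write_adjacency_csv(
            est.unsampled.astype(int), out / f"{est.method}_unsampled.csv", ids
        )


def write_posterior_params(post: PosteriorNetwork, out_dir, node_ids=None) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ids = _ids(post.n_nodes, node_ids)
    write_adjacency_csv(post.alpha, out / "posterior_alpha.csv", ids)
    write_adjacency_csv(post.beta, out / "posterior_beta.csv", ids)


def write_prior_json(prior: BetaPrior, path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "a": prior.a,
                "b": prior.b,
                "fit_log_marginal": prior.fit_log_marginal,
                "n_dyads_used": prior.n_dyads_used,
            },
            indent=2,
        )
    )


def write_metric_csv(
    md: MetricDistribution, path, method: str, node_ids=None
) -> None:
    ids = _ids(md.point.size, node_ids)
    pd.DataFrame(
        {
            "node_id": ids,
            "metric": md.metric,
            "point": md.point,
            "lower95": md.lower,
            "upper95": md.upper,
            "n_replicates": md.n_replicates,
            "method": method,
        }
    ).to_csv(path, index=False)


def write_run_metadata(path, **fields) -> None:
    """JSON sidecar recording seed, method, level, quantile rule, versions."""
    try:
        pkg_version = version("assocnet")
    except PackageNotFoundError:
        pkg_version = "unknown"
    meta = {"assocnet_version": pkg_version, "numpy_version": np.__version__}
    meta.update(fields)
    Path(path).write_text(json.dumps(meta, indent=2, default=str))
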