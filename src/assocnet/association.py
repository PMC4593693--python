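"""Dyadic sufficient statistics and the simple ratio index (SRI).

Whatever form observation data arrive in — complete sampling periods where
every dyad is scored together/apart, or a group-by-individual (GBI) matrix
of observed groups — everything downstream needs only two integers per dyad:

* ``d`` — the number of sampling units in which the pair co-occurred, and
* ``s`` — the number of sampling units in which the dyad was sampled at all
  (at least one member observed).

The SRI is d/s, the probability that the pair was together given that at
least one of them was seen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simnet import SamplingPeriods
from .util import check_symmetric_zero_diagonal, square_from_dyads


@dataclass(frozen=True)
class GroupByIndividual:
    """Gambit-of-the-group data: K observed groups × N individuals, 0/1."""

    matrix: np.ndarray
    individual_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.ndim != 2:
            raise ValueError("GBI matrix must be 2-D (groups × individuals)")
        if not np.isin(m, (0, 1)).all():
            raise ValueError("GBI entries must be binary")
        if len(self.individual_ids) != m.shape[1]:
            raise ValueError("one individual ID per column is required")
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("duplicate individual IDs")

    @property
    def n_groups(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class DyadCounts:
    """Per-dyad co-occurrence count d and sampling count s (symmetric N×N)."""

    d: np.ndarray
    s: np.ndarray

    def __post_init__(self) -> None:
        check_symmetric_zero_diagonal(self.d, "d")
        check_symmetric_zero_diagonal(self.s, "s")
        if self.d.shape != self.s.shape:
            raise ValueError("d and s must have the same shape")
        if np.any(self.d < 0) or np.any(self.d > self.s):
            raise ValueError("counts must satisfy 0 <= d <= s")

    @property
    def n_nodes(self) -> int:
        return self.d.shape[0]

    @property
    def unsampled(self) -> np.ndarray:
        """Boolean mask of off-diagonal dyads that were never sampled (s=0)."""
        mask = self.s == 0
        np.fill_diagonal(mask, False)
        return mask


def counts_from_periods(obs: SamplingPeriods) -> DyadCounts:
    """Reduce sampling periods to dyadic counts.

    In sampling-period data every dyad is scored in every period, so
    s = n_periods for all dyads and d counts the 1s.
    """
    d_flat = obs.together.sum(axis=0).astype(np.int64)
    d = square_from_dyads(d_flat, obs.n_nodes)
    s = np.full_like(d, obs.n_periods)
    np.fill_diagonal(s, 0)
    return DyadCounts(d=d, s=s)


def counts_from_gbi(gbi: GroupByIndividual) -> DyadCounts:
    """Reduce a group-by-individual matrix to dyadic counts.

    d(i,j) = number of groups containing both i and j; s(i,j) = number of
    groups containing i or j (each observed group is one sampling unit).
    """
    m = np.asarray(gbi.matrix, dtype=np.int64)
    co = m.T @ m
    n_obs = np.diagonal(co).copy()
    s = n_obs[:, None] + n_obs[None, :] - co
    d = co.copy()
    np.fill_diagonal(d, 0)
    np.fill_diagonal(s, 0)
    return DyadCounts(d=d, s=s)


def sri(counts: DyadCounts) -> np.ndarray:
    """Simple ratio index d/s as a symmetric weight matrix.

    Dyads that were never sampled (s=0) are reported as 0; use
    ``counts.unsampled`` to distinguish them from pairs that were sampled
    but never seen together.
    """
    w = np.zeros_like(counts.d, dtype=float)
    np.divide(counts.d, counts.s, out=w, where=counts.s > 0)
    np.fill_diagonal(w, 0.0)
    return w


def read_gbi_csv(path) -> GroupByIndividual:
    """Read a GBI matrix from CSV (rows = groups, header = individual IDs)."""
    df = pd.read_csv(path)
    ids = tuple(str(c) for c in df.columns)
    return GroupByIndividual(matrix=df.to_numpy(dtype=np.int64), individual_ids=ids)
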