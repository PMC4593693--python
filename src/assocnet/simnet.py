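"""Ground-truth social networks and simulated observation periods.

The generator builds weighted "real" networks in which each individual
carries a gregariousness score (Poisson-distributed sociality plus a small
offset so that nobody is a complete isolate) and, optionally, a clique
membership. The weight of a dyad — the probability that the pair associates
in any one sampling period — is the product of the two gregariousness
probabilities and a clique factor (high within cliques, low between them, or
a single uniform probability when cliques are disabled).

Observation data are then simulated as independent Bernoulli draws per dyad
per sampling period at the true edge weight, giving the binary
together/apart records that field studies of social associations produce.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .util import dyad_indices, dyads_from_square, square_from_dyads


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the ground-truth network generator.

    Parameters
    ----------
    n_nodes
        Number of individuals (N >= 2).
    cliques
        Whether the network contains community structure.
    n_cliques
        Number of cliques when ``cliques`` is enabled. Individuals are
        allocated to cliques independently and uniformly; empty cliques may
        occur.
    poisson_rate
        Rate λ of the Poisson distribution behind the gregariousness scores.
    gregariousness_offset
        Constant added to every raw score so no score is zero (isolate
        avoidance).
    p_within, p_between
        Association-probability factors for same-clique and different-clique
        dyads.
    p_nocliques
        Association-probability factor used for all dyads when cliques are
        disabled.
    seed
        Seed for the generator's own RNG; fixed seed means bit-reproducible
        output.
    """

    n_nodes: int = 15
    cliques: bool = True
    n_cliques: int = 5
    poisson_rate: float = 3.0
    gregariousness_offset: float = 0.05
    p_within: float = 0.9
    p_between: float = 0.1
    p_nocliques: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError(f"n_nodes must be >= 2, got {self.n_nodes}")
        if self.n_cliques < 1:
            raise ValueError(f"n_cliques must be >= 1, got {self.n_cliques}")
        if self.poisson_rate <= 0:
            raise ValueError("poisson_rate must be positive")
        if self.gregariousness_offset <= 0:
            raise ValueError("gregariousness_offset must be positive")
        for name in ("p_within", "p_between", "p_nocliques"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")


@dataclass(frozen=True)
class TrueNetwork:
    """A ground-truth weighted network.

    ``weights`` is the symmetric N×N matrix of true edge weights (association
    probabilities), zero on the diagonal. ``gregariousness`` holds the
    max-normalized per-node sociality probabilities (the maximum is exactly
    1). ``clique_id`` is None for networks without community structure.
    """

    gregariousness: np.ndarray
    weights: np.ndarray
    clique_id: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class SamplingPeriods:
    """Binary together/apart observations over S sampling periods.

    ``together`` has shape (S, n_dyads), dyads in row-major i<j order; every
    dyad is sampled in every period. Use :meth:`as_matrices` for the
    S×N×N symmetric view.
    """

    n_nodes: int
    together: np.ndarray  # (S, n_dyads) of {0, 1}

    def __post_init__(self) -> None:
        t = np.asarray(self.together)
        if t.ndim != 2:
            raise ValueError("together must be 2-D (periods × dyads)")
        if t.shape[0] < 1:
            raise ValueError("at least one sampling period is required")
        expected = self.n_nodes * (self.n_nodes - 1) // 2
        if t.shape[1] != expected:
            raise ValueError(
                f"expected {expected} dyads for {self.n_nodes} nodes, got {t.shape[1]}"
            )
        if not np.isin(t, (0, 1)).all():
            raise ValueError("observations must be binary")

    @property
    def n_periods(self) -> int:
        return self.together.shape[0]

    def as_matrices(self) -> np.ndarray:
        """Return the S × N × N symmetric 0/1 representation."""
        return np.stack(
            [square_from_dyads(row, self.n_nodes) for row in self.together]
        )

    def subset(self, period_index: np.ndarray) -> "SamplingPeriods":
        """Periods selected (with or without replacement) by index."""
        return SamplingPeriods(self.n_nodes, self.together[np.asarray(period_index)])


def generate_true_network(config: GeneratorConfig) -> TrueNetwork:
    """Generate a ground-truth weighted network.

    Draw order (fixed so seeds are portable): per-node Poisson scores first,
    then per-node clique labels (when cliques are enabled). The weight of
    dyad (i, j) is ``g_i * g_j * p`` with ``g`` the max-normalized
    gregariousness and ``p`` the within/between-clique (or uniform)
    association probability.
    """
    rng = np.random.default_rng(config.seed)
    scores = rng.poisson(config.poisson_rate, config.n_nodes) + config.gregariousness_offset
    gregariousness = scores / scores.max()

    clique_id: np.ndarray | None = None
    if config.cliques:
        clique_id = rng.integers(0, config.n_cliques, size=config.n_nodes)
        same = clique_id[:, None] == clique_id[None, :]
        p = np.where(same, config.p_within, config.p_between)
    else:
        p = config.p_nocliques

    weights = np.outer(gregariousness, gregariousness) * p
    np.fill_diagonal(weights, 0.0)
    return TrueNetwork(gregariousness=gregariousness, weights=weights, clique_id=clique_id)


def sample_observations(
    net: TrueNetwork, n_periods: int, seed: int | None = None
) -> SamplingPeriods:
    """Simulate S binary sampling periods from a true network.

    Each dyad is recorded together (1) or apart (0) independently in each
    period, with P(together) equal to the dyad's true edge weight. Draw
    order: dyads in row-major i<j order, all periods of a dyad
    consecutively.
    """
    if n_periods < 1:
        raise ValueError(f"n_periods must be >= 1, got {n_periods}")
    rng = np.random.default_rng(seed)
    w = dyads_from_square(net.weights)
    u = rng.random((w.size, n_periods))
    together = (u < w[:, None]).astype(np.uint8).T
    return SamplingPeriods(n_nodes=net.n_nodes, together=together)
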