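"""Common container for per-dyad edge estimates with interval bounds."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .util import check_symmetric_zero_diagonal


@dataclass(frozen=True)
class EdgeEstimateSet:
    """Per-dyad point estimates and interval bounds for one method.

    ``method`` is one of "bayes", "sri_bootstrap" or "clopper_pearson".
    ``point``, ``lower`` and ``upper`` are symmetric N×N matrices in [0, 1];
    ``level`` is the nominal interval mass (default 0.95). ``unsampled``
    marks dyads with no sampling information (s=0), for which the bounds are
    prior- or convention-driven rather than data-driven. ``metadata`` records
    method specifics (prior parameters, quantile rule, ...).
    """

    method: str
    point: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float = 0.95
    unsampled: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("point", "lower", "upper"):
            mat = getattr(self, name)
            check_symmetric_zero_diagonal(mat, name)
            off = ~np.eye(mat.shape[0], dtype=bool)
            if np.any(mat[off] < -1e-12) or np.any(mat[off] > 1 + 1e-12):
                raise ValueError(f"{name} entries must lie in [0, 1]")
        if np.any(self.lower > self.upper + 1e-12):
            raise ValueError("lower bound exceeds upper bound")
        if not 0.0 < self.level < 1.0:
            raise ValueError("level must be in (0, 1)")

    @property
    def n_nodes(self) -> int:
        return self.point.shape[0]

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower
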