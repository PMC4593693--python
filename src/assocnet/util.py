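"""Small shared helpers for dyad-indexed storage.

A network on ``n`` nodes has ``n*(n-1)/2`` unordered dyads. Throughout the
package dyads are enumerated in row-major upper-triangle order
(0,1), (0,2), ..., (0,n-1), (1,2), ... — the order :func:`numpy.triu_indices`
produces. This order is part of the seeding contract: every stochastic
operation that draws one value per dyad draws them in this order.
"""

from __future__ import annotations

import numpy as np


def n_dyads(n_nodes: int) -> int:
    return n_nodes * (n_nodes - 1) // 2


def dyad_indices(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Row and column indices of the dyads, row-major i<j order."""
    return np.triu_indices(n_nodes, k=1)


def dyads_from_square(mat: np.ndarray) -> np.ndarray:
    """Extract the upper-triangle (i<j) entries as a flat dyad vector."""
    return mat[np.triu_indices(mat.shape[0], k=1)]


def square_from_dyads(values: np.ndarray, n_nodes: int) -> np.ndarray:
    """Fold a flat dyad vector back into a symmetric zero-diagonal matrix."""
    values = np.asarray(values)
    out = np.zeros((n_nodes, n_nodes), dtype=values.dtype)
    iu, ju = np.triu_indices(n_nodes, k=1)
    out[iu, ju] = values
    out[ju, iu] = values
    return out


def check_symmetric_zero_diagonal(mat: np.ndarray, name: str = "matrix") -> None:
    mat = np.asarray(mat)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{name} must be square, got shape {mat.shape}")
    if not np.allclose(mat, mat.T):
        raise ValueError(f"{name} must be symmetric")
    if np.any(np.diagonal(mat) != 0):
        raise ValueError(f"{name} must have a zero diagonal")
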