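"""Assembly of the two-layer heterogeneous network.

The fused similarity matrices are degree-normalized
(``D^(-1/2) S D^(-1/2)``), then stacked with the association matrix
into the block matrix

    A_H = [[NSPG, A], [A^T, NSDG]]

The GCN input graph B is A_H with the similarity blocks scaled by the
penalty factor ``omega``, which controls how much the similarity layers
contribute during propagation relative to the association edges.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "symmetric_normalize",
    "assemble_hetero",
    "apply_penalty",
    "normalized_adjacency",
]


def symmetric_normalize(S: np.ndarray) -> np.ndarray:
    """D^(-1/2) S D^(-1/2) with D = diag(row sums)."""
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {S.shape}")
    deg = S.sum(axis=1)
    bad = np.nonzero(deg <= 0)[0]
    if bad.size:
        raise ValueError(f"zero row sum at index {int(bad[0])}; cannot normalize")
    inv_sqrt = 1.0 / np.sqrt(deg)
    return S * inv_sqrt[:, None] * inv_sqrt[None, :]


def assemble_hetero(NSPG: np.ndarray, NSDG: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Block matrix [[NSPG, A], [A^T, NSDG]]."""
    NSPG = np.asarray(NSPG, dtype=float)
    NSDG = np.asarray(NSDG, dtype=float)
    A = np.asarray(A, dtype=float)
    m, n = A.shape
    if NSPG.shape != (m, m) or NSDG.shape != (n, n):
        raise ValueError(
            f"block shapes incompatible: NSPG {NSPG.shape}, NSDG {NSDG.shape}, "
            f"A {A.shape}"
        )
    return np.block([[NSPG, A], [A.T, NSDG]])


def apply_penalty(A_H: np.ndarray, omega: float, M: int) -> np.ndarray:
    """Scale the two similarity blocks of A_H by omega; association
    blocks are untouched.  ``M`` is the number of piRNA rows."""
    if omega < 0:
        raise ValueError(f"penalty factor must be >= 0, got {omega}")
    A_H = np.asarray(A_H, dtype=float)
    B = A_H.copy()
    B[:M, :M] *= omega
    B[M:, M:] *= omega
    return B


def normalized_adjacency(B: np.ndarray) -> np.ndarray:
    """D^(-1/2) B D^(-1/2) with D the degree (row-sum) matrix of B.

    This is the propagation operator of every GCN layer; a zero-degree
    node is a hard error since its normalization is undefined.
    """
    return symmetric_normalize(B)
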