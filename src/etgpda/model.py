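"""Forward pass of the embedding-transformation GCN.

The encoder is an L-layer graph convolution over the penalty-weighted
heterogeneous network: ``H^(l) = ReLU(D^(-1/2) B D^(-1/2) H^(l-1)
W^(l-1))`` starting from ``H^(0) = [[0, A], [A^T, 0]]``.  The per-layer
embeddings are combined by learnable scalar layer-attention weights
(initialized to 1/(L+1) each), split into piRNA rows H_P and disease
rows H_D, and the piRNA embeddings are pushed through the bias-free
embedding-transformation (ETG) decoder k -> 2k -> 4k -> k with ReLU at
every layer.  Pair scores are cosine similarities between ETG(H_P) rows
and H_D rows (a raw dot-product mode is kept for ablation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .heterograph import normalized_adjacency

__all__ = [
    "ModelState",
    "ScoreMatrix",
    "init_model",
    "init_embedding",
    "gcn_layer",
    "attention_combine",
    "split_embeddings",
    "etg_forward",
    "etg_param_count",
    "score",
    "forward",
]


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class ScoreMatrix:
    """M x N pair scores; ``probabilities`` is the sigmoid view used by
    the loss and the thresholded metrics."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("score matrix contains non-finite values")

    @property
    def probabilities(self) -> np.ndarray:
        return sigmoid(self.values)


@dataclass
class ModelState:
    """All learnable parameters.

    ``gcn_weights[0]`` maps (M+N) -> k, later layers k -> k;
    ``attention`` holds one scalar per GCN layer; ``etg_weights`` are
    the three bias-free dense maps k -> 2k -> 4k -> k.
    """

    gcn_weights: list[np.ndarray]
    attention: np.ndarray
    etg_weights: list[np.ndarray]
    seed: int | None = None

    @property
    def n_layers(self) -> int:
        return len(self.gcn_weights)

    @property
    def embedding_dim(self) -> int:
        return self.gcn_weights[0].shape[1]

    def copy(self) -> "ModelState":
        return ModelState(
            [w.copy() for w in self.gcn_weights],
            self.attention.copy(),
            [w.copy() for w in self.etg_weights],
            self.seed,
        )


def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_model(
    M: int, N: int, k: int, n_layers: int, rng: np.random.Generator,
    seed: int | None = None,
) -> ModelState:
    """Xavier-uniform GCN/ETG weights; attention scalars at 1/(L+1)."""
    if k < 1 or n_layers < 1:
        raise ValueError("embedding_dim and n_layers must be >= 1")
    dims = [M + N] + [k] * n_layers
    gcn = [_xavier(rng, dims[l], dims[l + 1]) for l in range(n_layers)]
    attention = np.full(n_layers, 1.0 / (n_layers + 1))
    etg = [
        _xavier(rng, k, 2 * k),
        _xavier(rng, 2 * k, 4 * k),
        _xavier(rng, 4 * k, k),
    ]
    return ModelState(gcn, attention, etg, seed)


def init_embedding(A: np.ndarray) -> np.ndarray:
    """H^(0) = [[0, A], [A^T, 0]] — the bipartite incidence embedding."""
    A = np.asarray(A, dtype=float)
    m, n = A.shape
    h0 = np.zeros((m + n, m + n))
    h0[:m, m:] = A
    h0[m:, :m] = A.T
    return h0


def gcn_layer(B: np.ndarray, H_prev: np.ndarray, W: np.ndarray) -> np.ndarray:
    """One propagation step: ReLU(D^(-1/2) B D^(-1/2) H_prev W).

    ``B`` is the (possibly dropout-thinned) input graph; the degree
    normalization is recomputed from B.  Dropout itself is applied by
    the training loop (see :mod:`etgpda.training`).
    """
    Bn = normalized_adjacency(B)
    if H_prev.shape[0] != Bn.shape[0] or H_prev.shape[1] != W.shape[0]:
        raise ValueError(
            f"shape mismatch: B {B.shape}, H_prev {H_prev.shape}, W {W.shape}"
        )
    return _relu(Bn @ (H_prev @ W))


def attention_combine(H_list: list[np.ndarray], a: np.ndarray) -> np.ndarray:
    """Weighted sum of per-layer embeddings: H = sum_l a_l H^(l)."""
    a = np.asarray(a, dtype=float)
    if len(H_list) != a.shape[0]:
        raise ValueError("one attention weight per layer required")
    shape = H_list[0].shape
    if any(h.shape != shape for h in H_list):
        raise ValueError("per-layer embeddings must share a shape")
    out = np.zeros(shape)
    for w, h in zip(a, H_list):
        out += w * h
    return out


def split_embeddings(H: np.ndarray, M: int, N: int) -> tuple[np.ndarray, np.ndarray]:
    """First M rows -> piRNA embeddings, last N rows -> disease embeddings."""
    if H.shape[0] != M + N:
        raise ValueError(f"expected {M + N} rows, got {H.shape[0]}")
    return H[:M], H[M:]


def etg_forward(
    H_P: np.ndarray, etg_weights: list[np.ndarray], nonlinear: bool = True
) -> np.ndarray:
    """Bias-free decoder k -> 2k -> 4k -> k, ReLU after every map.

    ``nonlinear=False`` removes the activations (the linearized
    ablation variant).
    """
    x = np.asarray(H_P, dtype=float)
    for w in etg_weights:
        if x.shape[1] != w.shape[0]:
            raise ValueError(
                f"ETG weight shape {w.shape} incompatible with input "
                f"{x.shape}"
            )
        x = x @ w
        if nonlinear:
            x = _relu(x)
    return x


def etg_param_count(k: int) -> int:
    """Weight count of the bias-free ETG decoder: 14 k^2."""
    if k < 1:
        raise ValueError("embedding dimension must be >= 1")
    return k * 2 * k + 2 * k * 4 * k + 4 * k * k


def _row_normalize(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    norms = np.linalg.norm(x, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    return x / safe[:, None], norms


def score(
    etg_hp: np.ndarray, H_D: np.ndarray, mode: str = "cosine"
) -> ScoreMatrix:
    """Pair scores between transformed piRNA embeddings and disease
    embeddings; cosine rows with zero norm score 0 against everything."""
    if etg_hp.shape[1] != H_D.shape[1]:
        raise ValueError("embedding dimensions differ between piRNA and disease")
    if mode == "cosine":
        p, pn = _row_normalize(etg_hp)
        d, dn = _row_normalize(H_D)
        s = p @ d.T
        s[pn == 0, :] = 0.0
        s[:, dn == 0] = 0.0
    elif mode == "dot":
        s = etg_hp @ H_D.T
    else:
        raise ValueError(f"unknown score mode {mode!r}")
    return ScoreMatrix(s)


def forward(
    state: ModelState,
    Bn: np.ndarray,
    H0: np.ndarray,
    M: int,
    N: int,
    *,
    score_mode: str = "cosine",
    etg_nonlinear: bool = True,
) -> ScoreMatrix:
    """Full evaluation-time pass: GCN layers, attention, split, ETG, score.

    ``Bn`` is the already-normalized adjacency (no dropout at
    evaluation time); deterministic given (state, inputs).
    """
    h = H0
    layers = []
    for w in state.gcn_weights:
        h = _relu(Bn @ (h @ w))
        layers.append(h)
    combined = attention_combine(layers, state.attention)
    h_p, h_d = split_embeddings(combined, M, N)
    decoded = etg_forward(h_p, state.etg_weights, nonlinear=etg_nonlinear)
    return score(decoded, h_d, mode=score_mode)
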