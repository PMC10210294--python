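"""Fitting the model: weighted cross-entropy, Adam, cyclic LR, dropout.

The loss is the class-imbalance-weighted binary cross-entropy

    Loss = -(1/(N*M)) * ( mu * sum_{Y+} log a'_ij + sum_{Y-} log(1 - a'_ij) )

with ``mu = |Y-|/|Y+|`` computed on the training pairs and ``a'_ij``
the sigmoid of the cosine pair score.  Gradients are reverse-mode,
derived by hand for this fixed architecture (GCN layers, layer
attention, ETG decoder, cosine scoring) and verified against finite
differences in the test suite.  Optimization is full-graph Adam with a
triangular cyclic learning-rate schedule; node dropout thins graph
edges symmetrically and regular dropout thins embedding entries, both
with inverted (1/(1-rate)) rescaling and both identity at evaluation
time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import HyperParams
from .heterograph import normalized_adjacency
from .model import ModelState, init_embedding, init_model, sigmoid

__all__ = [
    "TrainState",
    "weighted_bce",
    "compute_mu",
    "cyclical_lr",
    "apply_node_dropout",
    "apply_regular_dropout",
    "loss_and_grads",
    "train",
]

_EPS = 1e-7  # probability clipping floor


@dataclass
class TrainState:
    """Bookkeeping for one fit: per-epoch loss and learning rate."""

    epochs_run: int = 0
    loss_history: list[float] = field(default_factory=list)
    lr_history: list[float] = field(default_factory=list)
    seed: int | None = None


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def compute_mu(A_train: np.ndarray) -> float:
    """mu = |Y-| / |Y+| over the training association matrix."""
    n_pos = int(np.sum(A_train == 1))
    n_neg = A_train.size - n_pos
    if n_pos == 0:
        raise ValueError("no positive pairs in training data; mu undefined")
    return n_neg / n_pos


def weighted_bce(a_prime: np.ndarray, A_train: np.ndarray, mu: float) -> float:
    """Weighted binary cross-entropy averaged over all M*N pairs.

    Probabilities are clipped to [eps, 1-eps] (eps = 1e-7) before the
    logs; with ``mu = 1`` this is the plain mean BCE.
    """
    if mu <= 0:
        raise ValueError(f"mu must be positive, got {mu}")
    a_prime = np.asarray(a_prime, dtype=float)
    A_train = np.asarray(A_train)
    if a_prime.shape != A_train.shape:
        raise ValueError("probability and label matrices differ in shape")
    pc = np.clip(a_prime, _EPS, 1.0 - _EPS)
    pos = A_train == 1
    total = mu * np.sum(np.log(pc[pos])) + np.sum(np.log(1.0 - pc[~pos]))
    return float(-total / A_train.size)


# ---------------------------------------------------------------------------
# schedule and dropout
# ---------------------------------------------------------------------------

def cyclical_lr(step: int, lr_base: float, lr_max: float, cycle_len: int) -> float:
    """Triangular wave: lr_base -> lr_max over half a cycle, back down
    over the other half."""
    if lr_base > lr_max:
        raise ValueError("lr_base must not exceed lr_max")
    if cycle_len < 2:
        raise ValueError("cycle_len must be >= 2")
    half = cycle_len / 2.0
    phase = step % cycle_len
    frac = phase / half if phase <= half else (cycle_len - phase) / half
    return lr_base + (lr_max - lr_base) * frac


def apply_node_dropout(
    B: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Zero symmetric edge entries of B with probability ``rate``,
    rescaling survivors by 1/(1-rate)."""
    if not 0 <= rate < 1:
        raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
    B = np.asarray(B, dtype=float)
    if rate == 0:
        return B.copy()
    keep = 1.0 - rate
    upper = np.triu(rng.random(B.shape) < keep)
    mask = (upper | upper.T).astype(float) / keep
    return B * mask


def apply_regular_dropout(
    H: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Elementwise inverted dropout on embedding entries."""
    if not 0 <= rate < 1:
        raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
    H = np.asarray(H, dtype=float)
    if rate == 0:
        return H.copy()
    keep = 1.0 - rate
    mask = (rng.random(H.shape) < keep).astype(float) / keep
    return H * mask


# ---------------------------------------------------------------------------
# reverse-mode gradients
# ---------------------------------------------------------------------------

def loss_and_grads(
    state: ModelState,
    Bn_eff: np.ndarray,
    H0: np.ndarray,
    A_train: np.ndarray,
    mu: float,
    *,
    score_mode: str = "cosine",
    etg_nonlinear: bool = True,
    reg_masks: list[np.ndarray] | None = None,
):
    """Loss and gradients of the full pass on the (dropout-thinned)
    normalized adjacency ``Bn_eff``.

    ``reg_masks`` are per-layer multiplicative embedding-dropout masks
    (scaling included); None disables regular dropout.  Returns
    ``(loss, grads)`` with ``grads`` keyed by ``gcn`` (list), ``attention``
    (vector) and ``etg`` (list).
    """
    A_train = np.asarray(A_train)
    m_rows, n_cols = A_train.shape
    L = state.n_layers
    a_vec = state.attention

    # ---- forward with caches -------------------------------------------
    xs, zs, hs = [], [], []
    h_prev = H0
    for l in range(L):
        x = h_prev * reg_masks[l] if reg_masks is not None else h_prev
        z = Bn_eff @ (x @ state.gcn_weights[l])
        h = np.maximum(z, 0.0)
        xs.append(x)
        zs.append(z)
        hs.append(h)
        h_prev = h

    combined = np.zeros_like(hs[0])
    for w, h in zip(a_vec, hs):
        combined += w * h
    h_p, h_d = combined[:m_rows], combined[m_rows:]

    ts, us = [h_p], []
    for w in state.etg_weights:
        u = ts[-1] @ w
        us.append(u)
        ts.append(np.maximum(u, 0.0) if etg_nonlinear else u)
    decoded = ts[-1]

    if score_mode == "cosine":
        pn = np.linalg.norm(decoded, axis=1)
        dn = np.linalg.norm(h_d, axis=1)
        p_unit = decoded / np.where(pn > 0, pn, 1.0)[:, None]
        d_unit = h_d / np.where(dn > 0, dn, 1.0)[:, None]
        s = p_unit @ d_unit.T
    elif score_mode == "dot":
        s = decoded @ h_d.T
    else:
        raise ValueError(f"unknown score mode {score_mode!r}")

    a_prime = sigmoid(s)
    loss = weighted_bce(a_prime, A_train, mu)

    # ---- backward ------------------------------------------------------
    size = A_train.size
    pos = A_train == 1
    unclipped = (a_prime > _EPS) & (a_prime < 1.0 - _EPS)
    g = np.zeros_like(s)
    g[pos & unclipped] = -(mu / size) * (1.0 - a_prime[pos & unclipped])
    g[(~pos) & unclipped] = (1.0 / size) * a_prime[(~pos) & unclipped]

    if score_mode == "cosine":
        d_punit = g @ d_unit
        d_dunit = g.T @ p_unit
        d_decoded = np.where(
            (pn > 0)[:, None],
            (d_punit - np.sum(d_punit * p_unit, axis=1, keepdims=True) * p_unit)
            / np.where(pn > 0, pn, 1.0)[:, None],
            0.0,
        )
        d_hd = np.where(
            (dn > 0)[:, None],
            (d_dunit - np.sum(d_dunit * d_unit, axis=1, keepdims=True) * d_unit)
            / np.where(dn > 0, dn, 1.0)[:, None],
            0.0,
        )
    else:
        d_decoded = g @ h_d
        d_hd = g.T @ decoded

    d_etg = [np.zeros_like(w) for w in state.etg_weights]
    d_t = d_decoded
    for j in range(len(state.etg_weights) - 1, -1, -1):
        d_u = d_t * (us[j] > 0) if etg_nonlinear else d_t
        d_etg[j] = ts[j].T @ d_u
        d_t = d_u @ state.etg_weights[j].T
    d_hp = d_t

    d_combined = np.vstack([d_hp, d_hd])
    d_attention = np.array([float(np.sum(d_combined * h)) for h in hs])
    d_hs = [w * d_combined for w in a_vec]

    d_gcn = [np.zeros_like(w) for w in state.gcn_weights]
    for l in range(L - 1, -1, -1):
        d_z = d_hs[l] * (zs[l] > 0)
        d_y = Bn_eff.T @ d_z
        d_gcn[l] = xs[l].T @ d_y
        if l > 0:
            d_x = d_y @ state.gcn_weights[l].T
            if reg_masks is not None:
                d_x = d_x * reg_masks[l]
            d_hs[l - 1] = d_hs[l - 1] + d_x

    return loss, {"gcn": d_gcn, "attention": d_attention, "etg": d_etg}


# ---------------------------------------------------------------------------
# optimizer and training loop
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, shapes, beta1=0.9, beta2=0.999, eps=1e-8):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray], lr: float):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / (1 - b1**self.t)
            v_hat = self.v[i] / (1 - b2**self.t)
            p -= lr * m_hat / (np.sqrt(v_hat) + self.eps)


def train(
    B: np.ndarray,
    A_train: np.ndarray,
    hp: HyperParams,
    seed: int | None = None,
) -> tuple[ModelState, TrainState]:
    """Fit the model on the penalty-weighted input graph ``B`` and the
    training association matrix.

    Deterministic given ``seed`` (defaults to ``hp.seed``); randomness
    is split into separate streams for weight init, node dropout and
    regular dropout.  Aborts with a diagnostic if the loss turns
    non-finite.
    """
    seed = hp.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    rng_init, rng_node, rng_reg = (np.random.default_rng(c) for c in ss.spawn(3))

    A_train = np.asarray(A_train, dtype=float)
    m_rows, n_cols = A_train.shape
    state = init_model(
        m_rows, n_cols, hp.embedding_dim, hp.gcn_layers, rng_init, seed=seed
    )
    train_state = TrainState(seed=seed)
    if hp.epochs == 0:
        return state, train_state

    Bn = normalized_adjacency(B)
    H0 = init_embedding(A_train)
    mu = compute_mu(A_train)
    cycle_len = max(2, hp.epochs // 4)

    params = list(state.gcn_weights) + [state.attention] + list(state.etg_weights)
    opt = _Adam([p.shape for p in params])
    L = hp.gcn_layers
    att_idx = L  # position of the attention vector in `params`

    for epoch in range(hp.epochs):
        Bn_eff = (
            apply_node_dropout(Bn, hp.node_dropout, rng_node)
            if hp.node_dropout > 0
            else Bn
        )
        if hp.regular_dropout > 0:
            keep = 1.0 - hp.regular_dropout
            reg_masks = []
            dim = H0.shape[1]
            n_nodes = H0.shape[0]
            for l in range(L):
                shape = (n_nodes, dim if l == 0 else hp.embedding_dim)
                reg_masks.append(
                    (rng_reg.random(shape) < keep).astype(float) / keep
                )
        else:
            reg_masks = None

        loss, grads = loss_and_grads(
            state,
            Bn_eff,
            H0,
            A_train,
            mu,
            score_mode=hp.score_mode,
            etg_nonlinear=hp.etg_nonlinear,
            reg_masks=reg_masks,
        )
        if not np.isfinite(loss):
            raise RuntimeError(
                f"non-finite loss at epoch {epoch}: {loss!r}; aborting"
            )

        grad_list = list(grads["gcn"]) + [grads["attention"]] + list(grads["etg"])
        if not hp.attention:
            grad_list[att_idx] = np.zeros_like(grad_list[att_idx])
        lr = cyclical_lr(epoch, hp.lr_lo, hp.lr_max, cycle_len)
        opt.step(params, grad_list, lr)

        train_state.loss_history.append(loss)
        train_state.lr_history.append(lr)
        train_state.epochs_run += 1

    return state, train_state
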