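"""Cross-validation, metrics, and candidate ranking.

Known positive pairs are split into five near-equal folds; each fold in
turn is hidden from training — zeroed in the association matrix, hence
absent from the GIP kernels and from every block of the heterogeneous
network — the model is retrained, and the held-out positives are scored
against the unknown pairs.  AUC uses midrank ties (the Mann-Whitney
normalization); accuracy, recall and specificity come from the
confusion matrix at a sigmoid-score threshold.  The whole five-fold
procedure is repeated with derived seeds and all fold results averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .data_io import AssociationTable, HyperParams
from .model import forward
from .pipeline import SimilarityBundle, fold_matrices, static_similarities
from .similarity import DiseaseDAG
from .training import train
from .heterograph import normalized_adjacency
from .model import init_embedding

__all__ = [
    "FoldSplit",
    "MetricsReport",
    "make_folds",
    "compute_metrics",
    "cross_validate",
    "rank_candidates",
    "score_table",
]

Pair = tuple[int, int]


@dataclass
class FoldSplit:
    """Disjoint groups of positive pairs; sizes differ by at most one."""

    groups: list[list[Pair]]
    seed: int

    def __iter__(self):
        return iter(self.groups)

    def __len__(self):
        return len(self.groups)


@dataclass
class MetricsReport:
    """Per-fold and averaged AUC / accuracy / recall / specificity."""

    fold_metrics: list[dict] = field(default_factory=list)
    threshold: float = 0.5
    repeats: int = 0

    _KEYS = ("auc", "accuracy", "recall", "specificity")

    def add(self, repeat: int, fold: int, metrics: Mapping[str, float]) -> None:
        entry = {"repeat": repeat, "fold": fold}
        entry.update({k: float(metrics[k]) for k in self._KEYS})
        self.fold_metrics.append(entry)

    @property
    def means(self) -> dict[str, float]:
        return {
            k: float(np.mean([m[k] for m in self.fold_metrics]))
            for k in self._KEYS
        }

    def sem(self, key: str = "auc") -> float:
        vals = np.array([m[key] for m in self.fold_metrics])
        if vals.size < 2:
            return float("nan")
        return float(vals.std(ddof=1) / np.sqrt(vals.size))

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "repeats": self.repeats,
            "means": self.means,
            "folds": self.fold_metrics,
        }


def make_folds(positives: Sequence[Pair], k: int = 5, seed: int = 0) -> FoldSplit:
    """Seeded shuffle then round-robin assignment into k groups."""
    positives = sorted(positives)
    if len(positives) < k:
        raise ValueError(
            f"need at least {k} positive pairs for {k}-fold CV, got "
            f"{len(positives)}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(positives))
    groups: list[list[Pair]] = [[] for _ in range(k)]
    for pos, idx in enumerate(order):
        groups[pos % k].append(positives[idx])
    return FoldSplit(groups, seed)


def compute_metrics(
    scores: np.ndarray,
    test_positives: Sequence[Pair],
    negatives: Sequence[Pair],
    threshold: float = 0.5,
) -> dict[str, float]:
    """AUC (midrank ties) plus thresholded accuracy/recall/specificity.

    ``scores`` must be on the probability scale for the threshold to be
    meaningful; AUC is invariant to any monotone rescaling.
    """
    if len(test_positives) == 0 or len(negatives) == 0:
        raise ValueError("need at least one positive and one negative pair")
    scores = np.asarray(scores, dtype=float)
    pos = np.array([scores[i, j] for i, j in test_positives])
    neg = np.array([scores[i, j] for i, j in negatives])

    ranks = rankdata(np.concatenate([pos, neg]))
    n_pos, n_neg = pos.size, neg.size
    auc = (ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    tp = int(np.sum(pos >= threshold))
    fn = n_pos - tp
    tn = int(np.sum(neg < threshold))
    fp = n_neg - tn
    return {
        "auc": float(auc),
        "accuracy": (tp + tn) / (n_pos + n_neg),
        "recall": tp / n_pos,
        "specificity": tn / n_neg,
    }


def score_table(
    B: np.ndarray, A_train: np.ndarray, state, hp: HyperParams
) -> np.ndarray:
    """Evaluation-time score matrix (probability scale) for a fitted model."""
    m, n = A_train.shape
    bn = normalized_adjacency(B)
    h0 = init_embedding(A_train)
    sm = forward(
        state, bn, h0, m, n,
        score_mode=hp.score_mode, etg_nonlinear=hp.etg_nonlinear,
    )
    return sm.probabilities


def cross_validate(
    table: AssociationTable,
    hp: HyperParams,
    *,
    sequences: Mapping[str, str] | None = None,
    dag: DiseaseDAG | None = None,
    repeats: int = 10,
    n_folds: int = 5,
    negatives: str = "all_unknown",
    seed: int | None = None,
    scorer: Callable[[np.ndarray], np.ndarray] | None = None,
    bundle: SimilarityBundle | None = None,
) -> MetricsReport:
    """Repeated five-fold cross-validation with leakage-safe recomputation.

    Per fold the test positives are zeroed in the training matrix and
    everything downstream (GIP kernels, fusions, network, model) is
    recomputed from that masked matrix.  ``negatives`` selects the
    negative pool for metrics: every never-known pair (``all_unknown``)
    or a seeded 1:1 sample of it (``sampled_1to1``).  ``scorer``, when
    given, replaces training+scoring with a callable mapping the
    training matrix to a probability matrix (used for oracle tests).
    """
    if negatives not in ("all_unknown", "sampled_1to1"):
        raise ValueError(f"unknown negatives policy {negatives!r}")
    seed = hp.seed if seed is None else seed
    if bundle is None:
        bundle = static_similarities(table, sequences, dag, hp)

    unknown_pairs = [tuple(p) for p in zip(*np.nonzero(table.A == 0))]
    positives = sorted(table.positives)
    report = MetricsReport(threshold=hp.threshold, repeats=repeats)
    ss = np.random.SeedSequence(seed)
    repeat_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(repeats)]

    for rep, rep_seed in enumerate(repeat_seeds):
        folds = make_folds(positives, n_folds, rep_seed)
        for fold_idx, test_pairs in enumerate(folds):
            A_train = table.A.copy().astype(float)
            rows, cols = zip(*test_pairs)
            A_train[rows, cols] = 0.0

            if scorer is not None:
                probs = scorer(A_train)
            else:
                mats = fold_matrices(A_train, bundle, hp)
                fold_seed = (rep_seed + 7919 * fold_idx) % (2**31)
                state, _ = train(mats["B"], A_train, hp, seed=fold_seed)
                probs = score_table(mats["B"], A_train, state, hp)

            if negatives == "sampled_1to1":
                rng = np.random.default_rng(rep_seed + fold_idx)
                take = min(len(test_pairs), len(unknown_pairs))
                idx = rng.choice(len(unknown_pairs), size=take, replace=False)
                neg_pairs = [unknown_pairs[i] for i in idx]
            else:
                neg_pairs = unknown_pairs

            metrics = compute_metrics(probs, test_pairs, neg_pairs, hp.threshold)
            report.add(rep, fold_idx, metrics)
    return report


def rank_candidates(
    scores: np.ndarray,
    table: AssociationTable,
    disease_id: str,
    *,
    exclude_known: bool = True,
    top_k: int = 10,
) -> list[tuple[str, float]]:
    """Top-k piRNAs for one disease, descending score, ties by piRNA id."""
    if disease_id not in table.disease_ids:
        raise KeyError(f"unknown disease {disease_id!r}")
    j = table.disease_ids.index(disease_id)
    scores = np.asarray(scores, dtype=float)
    entries = [
        (table.pirna_ids[i], float(scores[i, j]))
        for i in range(table.M)
        if not (exclude_known and table.A[i, j] == 1)
    ]
    entries.sort(key=lambda e: (-e[1], e[0]))
    return entries[:top_k]
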