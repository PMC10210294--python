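"""Synthetic worlds with planted, recoverable structure.

Real piRNA-disease data could not ship with the package, so every stage
is exercised on generated datasets that plant the one assumption the
model exploits: similar piRNAs tend to associate with the same
diseases.  piRNAs fall into latent clusters sharing an implanted
sequence motif; diseases fall into clusters hanging under a common DAG
ancestor; associations are i.i.d. Bernoulli draws from a block affinity
table over the (piRNA cluster, disease cluster) grid.  Regeneration
from (seed, params) is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data_io import AssociationTable
from .similarity import DiseaseDAG

__all__ = [
    "SyntheticWorld",
    "gen_sequences",
    "gen_dag",
    "gen_associations",
    "benchmark_world",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SyntheticWorld:
    """A complete generated dataset plus its hidden ground truth."""

    sequences: dict[str, str]
    dag: DiseaseDAG
    table: AssociationTable
    pirna_clusters: list[int]
    disease_clusters: list[int]
    affinity: np.ndarray
    hidden_positives: set[tuple[int, int]]
    seed: int
    preset: str = "custom"


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def gen_sequences(
    n: int,
    length_range: tuple[int, int] = (26, 32),
    n_clusters: int = 3,
    motif_len: int = 8,
    seed: int = 0,
) -> tuple[dict[str, str], list[int]]:
    """Random sequences with one shared motif implanted per cluster."""
    if not n >= n_clusters >= 1:
        raise ValueError("need n >= n_clusters >= 1")
    lo, hi = length_range
    if motif_len > lo:
        raise ValueError(
            f"motif length {motif_len} exceeds minimum sequence length {lo}"
        )
    rng = np.random.default_rng(seed)
    motifs = [_random_seq(rng, motif_len) for _ in range(n_clusters)]
    sequences: dict[str, str] = {}
    labels: list[int] = []
    for i in range(n):
        cluster = i % n_clusters
        labels.append(cluster)
        length = int(rng.integers(lo, hi + 1))
        seq = list(_random_seq(rng, length))
        pos = int(rng.integers(0, length - motif_len + 1))
        seq[pos : pos + motif_len] = motifs[cluster]
        sequences[f"piR-syn-{i:05d}"] = "".join(seq)
    return sequences, labels


def gen_dag(
    n_diseases: int,
    n_clusters: int = 3,
    depth: int = 2,
    seed: int = 0,
) -> tuple[DiseaseDAG, list[int]]:
    """One root; each cluster's diseases hang under a distinct hub
    ancestor placed ``depth`` levels below the root."""
    if n_diseases < 1 or n_clusters < 1 or depth < 1:
        raise ValueError("n_diseases, n_clusters and depth must be positive")
    if n_diseases < n_clusters:
        raise ValueError("need at least one disease per cluster")
    edges: list[tuple[str, str]] = []
    for c in range(n_clusters):
        chain = ["ROOT"] + [f"NODE-{c}-{d}" for d in range(depth)]
        for child, parent in zip(chain[1:], chain[:-1]):
            edges.append((child, parent))
    labels: list[int] = []
    for j in range(n_diseases):
        cluster = j % n_clusters
        labels.append(cluster)
        edges.append((f"D{j:03d}", f"NODE-{cluster}-{depth - 1}"))
    return DiseaseDAG(edges), labels


def gen_associations(
    pirna_clusters: Sequence[int],
    disease_clusters: Sequence[int],
    affinity: np.ndarray,
    seed: int = 0,
    hide_fraction: float = 0.0,
) -> tuple[AssociationTable, set[tuple[int, int]]]:
    """Bernoulli(affinity[cluster(p), cluster(d)]) association draws.

    ``hide_fraction`` removes that share of drawn positives from the
    table and returns them separately as evaluation truth.
    """
    affinity = np.asarray(affinity, dtype=float)
    if affinity.min() < 0 or affinity.max() > 1:
        raise ValueError("affinity entries must be in [0, 1]")
    rng = np.random.default_rng(seed)
    m, n = len(pirna_clusters), len(disease_clusters)
    probs = affinity[np.asarray(pirna_clusters)[:, None],
                     np.asarray(disease_clusters)[None, :]]
    A = (rng.random((m, n)) < probs).astype(np.int8)

    hidden: set[tuple[int, int]] = set()
    if hide_fraction > 0:
        pos = np.argwhere(A == 1)
        n_hide = int(round(hide_fraction * len(pos)))
        idx = rng.choice(len(pos), size=n_hide, replace=False)
        for i, j in pos[idx]:
            A[i, j] = 0
            hidden.add((int(i), int(j)))

    pirna_ids = [f"piR-syn-{i:05d}" for i in range(m)]
    disease_ids = [f"D{j:03d}" for j in range(n)]
    return AssociationTable(pirna_ids, disease_ids, A), hidden


_PRESETS = {
    # name: (n_pirna, n_disease, n_p_clusters, n_d_clusters, within, between)
    "small": (60, 8, 3, 2, 0.35, 0.05),
    "default": (500, 20, 3, 3, 0.30, 0.02),
}


def benchmark_world(
    preset: str = "default", seed: int = 0, hide_fraction: float = 0.0
) -> SyntheticWorld:
    """Standard worlds: ``small`` (60 piRNAs x 8 diseases, unit-test
    scale) and ``default`` (500 x 20 with a 3x3 block affinity of 0.30
    within / 0.02 between clusters)."""
    if preset not in _PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(_PRESETS)}")
    n_p, n_d, kp, kd, within, between = _PRESETS[preset]
    ss = np.random.SeedSequence(seed)
    s_seq, s_dag, s_assoc = (
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3)
    )
    sequences, p_labels = gen_sequences(n_p, n_clusters=kp, seed=s_seq)
    dag, d_labels = gen_dag(n_d, n_clusters=kd, seed=s_dag)
    affinity = np.full((kp, kd), between)
    for c in range(min(kp, kd)):
        affinity[c, c] = within
    table, hidden = gen_associations(
        p_labels, d_labels, affinity, seed=s_assoc, hide_fraction=hide_fraction
    )
    return SyntheticWorld(
        sequences=sequences,
        dag=dag,
        table=table,
        pirna_clusters=p_labels,
        disease_clusters=d_labels,
        affinity=affinity,
        hidden_positives=hidden,
        seed=seed,
        preset=preset,
    )
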