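"""Similarity kernels for piRNAs and diseases.

Three families of pairwise similarity feed the heterogeneous network:

* **sequence similarity** — global (Needleman–Wunsch) alignment scores
  between piRNA sequences, min–max standardized to [0, 1] with the
  diagonal forced to 1;
* **Gaussian interaction-profile (GIP) kernel** — ``exp(-phi * ||V(a) -
  V(b)||^2)`` on rows/columns of the binary association matrix, with the
  bandwidth ``phi`` set to the reciprocal of the mean squared profile
  norm;
* **DAG semantic similarity** — a Wang-style measure on MeSH-like
  disease DAGs where each ancestor's contribution decays by a factor
  ``delta`` per layer and shared-ancestor contributions are summed and
  normalized.

The two fusion rules pick the sequence/semantic value wherever both
entities carry that kind of evidence and fall back to the GIP kernel
elsewhere.
"""

from __future__ import annotations

import warnings
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from Bio import Align
from scipy.spatial.distance import cdist

__all__ = [
    "DiseaseDAG",
    "nw_score",
    "minmax_standardize",
    "pirna_sequence_similarity",
    "gip_kernel",
    "dag_contributions",
    "semantic_similarity",
    "semantic_similarity_matrix",
    "fuse_similarity",
]


class DegenerateMatrixWarning(UserWarning):
    """Raised (as a warning) when a similarity matrix is constant."""


# ---------------------------------------------------------------------------
# disease DAG
# ---------------------------------------------------------------------------

class DiseaseDAG:
    """A disease hierarchy stored as child -> parent edges.

    ``ancestors(d)`` is the node set T_d: the disease itself plus every
    node reachable by repeatedly following parent edges.  Contribution
    maps (DV) decay by ``delta`` per hierarchy layer, taking the maximum
    over descendant paths when several exist.
    """

    def __init__(self, edges: Iterable[tuple[str, str]], nodes: Iterable[str] = ()):
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edges)  # direction: child -> parent
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(
                f"disease hierarchy contains a cycle through {cycle[0][0]!r}"
            )
        self._g = g

    @property
    def node_list(self) -> list[str]:
        return list(self._g.nodes)

    def __contains__(self, disease: str) -> bool:
        return disease in self._g

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    def parents(self, node: str) -> list[str]:
        return list(self._g.successors(node))

    def children(self, node: str) -> list[str]:
        return list(self._g.predecessors(node))

    def ancestors(self, disease: str) -> frozenset[str]:
        """T_d: the disease plus all its ancestors."""
        if disease not in self._g:
            raise KeyError(f"disease {disease!r} not in DAG")
        return frozenset(nx.descendants(self._g, disease)) | {disease}

    def contributions(self, disease: str, delta: float) -> dict[str, float]:
        return dag_contributions(self, disease, delta)


def dag_contributions(dag: DiseaseDAG, disease: str, delta: float) -> dict[str, float]:
    """Semantic contribution map DV_d over T_d.

    DV_d(d) = 1; each ancestor t gets ``max over children c of t inside
    T_d of delta * DV_d(c)`` — i.e. the best (least-decayed) path from
    the disease up to t.
    """
    if not 0 < delta <= 1:
        raise ValueError(f"contribution factor must be in (0, 1], got {delta}")
    closure = dag.ancestors(disease)

    dv: dict[str, float] = {}

    def value(node: str) -> float:
        if node in dv:
            return dv[node]
        if node == disease:
            dv[node] = 1.0
            return 1.0
        best = max(
            delta * value(c) for c in dag.children(node) if c in closure
        )
        dv[node] = best
        return best

    # iterate in an order that keeps recursion shallow: nodes nearer the
    # disease first (plain recursion is fine on DAGs of MeSH-like depth)
    for node in closure:
        value(node)
    return dv


def semantic_similarity(dag: DiseaseDAG, d_a: str, d_b: str, delta: float) -> float:
    """Wang-style semantic similarity between two diseases in [0, 1]."""
    if d_a not in dag:
        raise KeyError(f"disease {d_a!r} not in DAG")
    if d_b not in dag:
        raise KeyError(f"disease {d_b!r} not in DAG")
    if d_a == d_b:
        return 1.0
    dv_a = dag_contributions(dag, d_a, delta)
    dv_b = dag_contributions(dag, d_b, delta)
    common = set(dv_a) & set(dv_b)
    if not common:
        return 0.0
    shared = sum(dv_a[t] + dv_b[t] for t in common)
    total = sum(dv_a.values()) + sum(dv_b.values())
    return shared / total


def semantic_similarity_matrix(
    dag: DiseaseDAG, disease_ids: Sequence[str], delta: float
) -> np.ndarray:
    """Pairwise semantic similarity over ``disease_ids`` (all must be in the DAG)."""
    n = len(disease_ids)
    sd = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            sd[i, j] = sd[j, i] = semantic_similarity(
                dag, disease_ids[i], disease_ids[j], delta
            )
    return sd


# ---------------------------------------------------------------------------
# sequence similarity
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def _aligner(match: float, mismatch: float, gap: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap  # linear gap penalty
    return aligner


def nw_score(
    seq_a: str,
    seq_b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -1.0,
) -> float:
    """Optimal global-alignment score under a linear gap penalty."""
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    return float(_aligner(match, mismatch, gap).score(seq_a, seq_b))


def minmax_standardize(raw: np.ndarray) -> np.ndarray:
    """(x - min) / (max - min) over all entries; constant input maps to zeros."""
    raw = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(raw)):
        raise ValueError("matrix has non-finite entries")
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        warnings.warn(
            "degenerate standardization: all scores equal; returning zeros",
            DegenerateMatrixWarning,
            stacklevel=2,
        )
        return np.zeros_like(raw)
    return (raw - lo) / (hi - lo)


def pirna_sequence_similarity(
    sequences: Sequence[str],
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -1.0,
) -> np.ndarray:
    """Standardized pairwise alignment-score matrix SP with unit diagonal.

    The raw score matrix (including self-alignments) is min-max
    standardized over all entries, then the diagonal is overwritten
    with 1.
    """
    m = len(sequences)
    if m == 0:
        raise ValueError("no sequences given")
    raw = np.empty((m, m))
    for i in range(m):
        for j in range(i, m):
            raw[i, j] = raw[j, i] = nw_score(
                sequences[i], sequences[j], match, mismatch, gap
            )
    if m == 1:
        return np.ones((1, 1))
    sp = minmax_standardize(raw)
    np.fill_diagonal(sp, 1.0)
    return sp


# ---------------------------------------------------------------------------
# GIP kernel
# ---------------------------------------------------------------------------

def gip_kernel(A: np.ndarray, axis: str) -> np.ndarray:
    """Gaussian interaction-profile kernel over rows (piRNAs) or columns (diseases).

    The bandwidth is ``phi = 1 / mean_k ||V(k)||^2`` with the mean taken
    over all profiles of the chosen axis; entries are
    ``exp(-phi * ||V(a) - V(b)||^2)``.
    """
    A = np.asarray(A, dtype=float)
    if axis == "pirna":
        profiles = A
    elif axis == "disease":
        profiles = A.T
    else:
        raise ValueError(f"axis must be 'pirna' or 'disease', got {axis!r}")
    mean_sq = float(np.mean(np.sum(profiles**2, axis=1)))
    if mean_sq == 0.0:
        raise ValueError("all interaction profiles are zero; GIP bandwidth undefined")
    phi = 1.0 / mean_sq
    d2 = cdist(profiles, profiles, metric="sqeuclidean")
    g = np.exp(-phi * d2)
    return (g + g.T) / 2.0  # exact symmetry despite fp round-off


# ---------------------------------------------------------------------------
# fusion
# ---------------------------------------------------------------------------

def fuse_similarity(
    primary: np.ndarray, gip: np.ndarray, available_mask: np.ndarray
) -> np.ndarray:
    """Select the primary (sequence/semantic) similarity where both
    entities carry that evidence, GIP elsewhere; unit diagonal."""
    primary = np.asarray(primary, dtype=float)
    gip = np.asarray(gip, dtype=float)
    mask = np.asarray(available_mask, dtype=bool)
    if primary.shape != gip.shape or primary.shape != mask.shape:
        raise ValueError(
            f"shape mismatch: primary {primary.shape}, gip {gip.shape}, "
            f"mask {mask.shape}"
        )
    fused = np.where(mask, primary, gip)
    np.fill_diagonal(fused, 1.0)
    return fused


def availability_mask(available: Sequence[bool]) -> np.ndarray:
    """Pairwise mask: True where both entities have primary-similarity data."""
    a = np.asarray(available, dtype=bool)
    return np.outer(a, a)
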