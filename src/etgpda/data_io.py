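"""Readers and writers for the external formats, plus the core data model.

Formats handled here:

* two-column TSV of known piRNA-disease association pairs,
* FASTA piRNA sequences (RNA or DNA alphabet; ``U`` is normalized to
  ``T`` so one aligner scoring scheme covers both),
* two-column TSV edge list (``child<TAB>parent``) describing a
  MeSH-style disease DAG,
* score TSV and metrics JSON outputs.

Internal indices are 0-based; every file written carries string ids
only.  Vocabulary order is first appearance in the association file and
is never reordered by sequence or DAG files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .similarity import DiseaseDAG

__all__ = [
    "AssociationTable",
    "HyperParams",
    "ParseError",
    "read_associations",
    "read_fasta",
    "read_dag",
    "write_associations",
    "write_fasta",
    "write_dag",
    "write_scores",
    "write_metrics",
]


class ParseError(ValueError):
    """An input file violated its format contract."""


_SEQ_ALPHABET = frozenset("ACGTN")


# ---------------------------------------------------------------------------
# core data model
# ---------------------------------------------------------------------------

@dataclass
class AssociationTable:
    """Binary piRNA x disease association matrix with id vocabularies.

    ``A[i, j] == 1`` iff the pair (pirna_ids[i], disease_ids[j]) is a
    known association; every other pair is *unknown*, not negative.
    """

    pirna_ids: list[str]
    disease_ids: list[str]
    A: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=np.int8)
        m, n = self.A.shape
        if m != len(self.pirna_ids) or n != len(self.disease_ids):
            raise ValueError("matrix shape does not match vocabularies")
        if len(set(self.pirna_ids)) != m or len(set(self.disease_ids)) != n:
            raise ValueError("duplicate identifiers in vocabulary")
        if not np.isin(self.A, (0, 1)).all():
            raise ValueError("association matrix must be binary")

    @property
    def M(self) -> int:
        return len(self.pirna_ids)

    @property
    def N(self) -> int:
        return len(self.disease_ids)

    @property
    def positives(self) -> set[tuple[int, int]]:
        """S^P as 0-based (row, col) index pairs."""
        return set(zip(*np.nonzero(self.A)))

    @property
    def n_positive(self) -> int:
        return int(self.A.sum())

    @property
    def n_unknown(self) -> int:
        """|S^U| — all pairs not known to be associated."""
        return self.M * self.N - self.n_positive

    @classmethod
    def from_pairs(cls, pairs: Sequence[tuple[str, str]]) -> "AssociationTable":
        """Build a table from (piRNA id, disease id) pairs.

        Duplicates collapse to a single positive; vocabularies follow
        first-appearance order.
        """
        pirna_ids: list[str] = []
        disease_ids: list[str] = []
        p_index: dict[str, int] = {}
        d_index: dict[str, int] = {}
        coords: set[tuple[int, int]] = set()
        for pid, did in pairs:
            if pid not in p_index:
                p_index[pid] = len(pirna_ids)
                pirna_ids.append(pid)
            if did not in d_index:
                d_index[did] = len(disease_ids)
                disease_ids.append(did)
            coords.add((p_index[pid], d_index[did]))
        A = np.zeros((len(pirna_ids), len(disease_ids)), dtype=np.int8)
        for i, j in coords:
            A[i, j] = 1
        return cls(pirna_ids, disease_ids, A)

    def masked(self, pairs: Sequence[tuple[int, int]]) -> "AssociationTable":
        """Copy with the given (row, col) positives zeroed (e.g. a test fold)."""
        A = self.A.copy()
        for i, j in pairs:
            A[i, j] = 0
        return AssociationTable(list(self.pirna_ids), list(self.disease_ids), A)


# ---------------------------------------------------------------------------
# hyper-parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HyperParams:
    """Everything tunable, with the defaults used throughout.

    ``embedding_dim`` (k) and ``lr_max`` follow the reported best
    values (16 and 0.01); dropouts follow the reported optimum
    (node 0.6 / regular 0.4); ``contribution_factor`` is the standard
    0.5 per-layer semantic decay.  ``penalty`` scales the similarity
    blocks of the GCN input graph; ``gcn_layers`` and ``epochs`` are
    package defaults (3 and 400).
    """

    embedding_dim: int = 16
    gcn_layers: int = 3
    penalty: float = 1.0
    lr_max: float = 0.01
    lr_base: float | None = None  # None -> lr_max / 10
    epochs: int = 400
    node_dropout: float = 0.6
    regular_dropout: float = 0.4
    nw_match: float = 1.0
    nw_mismatch: float = -1.0
    nw_gap: float = -1.0
    contribution_factor: float = 0.5
    threshold: float = 0.5
    score_mode: str = "cosine"  # "cosine" | "dot"
    etg_nonlinear: bool = True
    attention: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.embedding_dim < 1:
            raise ValueError("embedding_dim must be >= 1")
        if self.gcn_layers < 1:
            raise ValueError("gcn_layers must be >= 1")
        if self.penalty < 0:
            raise ValueError("penalty must be >= 0")
        if not 0 <= self.node_dropout < 1 or not 0 <= self.regular_dropout < 1:
            raise ValueError("dropout rates must be in [0, 1)")
        if not 0 < self.contribution_factor <= 1:
            raise ValueError("contribution_factor must be in (0, 1]")
        if self.lr_base is not None and self.lr_base > self.lr_max:
            raise ValueError("lr_base must not exceed lr_max")
        if self.score_mode not in ("cosine", "dot"):
            raise ValueError("score_mode must be 'cosine' or 'dot'")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")

    @property
    def lr_lo(self) -> float:
        return self.lr_max / 10.0 if self.lr_base is None else self.lr_base

    @classmethod
    def from_mapping(cls, cfg: Mapping) -> "HyperParams":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(cfg) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**cfg)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_associations(path: str | Path) -> AssociationTable:
    """Read a 2+ column TSV of (piRNA id, disease id) pairs.

    Duplicate pairs collapse to one positive; vocabularies are built in
    first-appearance order.
    """
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise ParseError(
                    f"{path}:{lineno}: expected at least two tab-separated "
                    f"columns (piRNA id, disease id)"
                )
            pairs.append((fields[0].strip(), fields[1].strip()))
    if not pairs:
        raise ParseError(f"{path}: no association pairs found")
    return AssociationTable.from_pairs(pairs)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read piRNA sequences; uppercase, U mapped to T, ids deduplicated.

    Two records with the same id are allowed only if their sequences
    agree after normalization.
    """
    path = Path(path)
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper().replace("U", "T")
        bad = set(seq) - _SEQ_ALPHABET
        if bad:
            raise ParseError(
                f"{path}: record {record.id!r} has unexpected characters "
                f"{sorted(bad)}"
            )
        if record.id in sequences and sequences[record.id] != seq:
            raise ParseError(
                f"{path}: id {record.id!r} appears twice with conflicting "
                f"sequences"
            )
        sequences[record.id] = seq
    return sequences


def read_dag(path: str | Path) -> DiseaseDAG:
    """Read a child<TAB>parent edge list into a disease DAG."""
    path = Path(path)
    edges: list[tuple[str, str]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise ParseError(
                    f"{path}:{lineno}: expected child<TAB>parent"
                )
            edges.append((fields[0].strip(), fields[1].strip()))
    return DiseaseDAG(edges)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_associations(table: AssociationTable, path: str | Path) -> None:
    path = Path(path)
    rows = sorted(table.positives)
    with path.open("w") as fh:
        for i, j in rows:
            fh.write(f"{table.pirna_ids[i]}\t{table.disease_ids[j]}\n")


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for pid, seq in sequences.items():
            fh.write(f">{pid}\n{seq}\n")


def write_dag(dag: DiseaseDAG, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for node in dag.node_list:
            for parent in dag.parents(node):
                fh.write(f"{node}\t{parent}\n")


def write_scores(
    scores: np.ndarray,
    pirna_ids: Sequence[str],
    disease_ids: Sequence[str],
    path: str | Path,
) -> None:
    """Write a score TSV sorted by disease, then descending score, ties
    broken by piRNA id."""
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("score matrix contains non-finite values")
    if scores.shape != (len(pirna_ids), len(disease_ids)):
        raise ValueError("score matrix shape does not match vocabularies")
    df = pd.DataFrame(scores, index=list(pirna_ids), columns=list(disease_ids))
    long = df.stack().rename_axis(["pirna_id", "disease_id"]).reset_index(name="score")
    long = long.sort_values(
        ["disease_id", "score", "pirna_id"], ascending=[True, False, True]
    )
    long.to_csv(path, sep="\t", index=False)


def write_metrics(report, path: str | Path) -> None:
    """Serialize a MetricsReport (or any mapping) as JSON."""
    payload = report.to_dict() if hasattr(report, "to_dict") else dict(report)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    text = json.dumps(payload, indent=2, default=_default)
    if any(
        isinstance(v, float) and not math.isfinite(v)
        for v in _flatten(payload)
    ):
        raise ValueError("metrics contain non-finite values")
    Path(path).write_text(text + "\n")


def _flatten(obj):
    if isinstance(obj, dict):
        for v in obj.values():
            yield from _flatten(v)
    elif isinstance(obj, (list, tuple)):
        for v in obj:
            yield from _flatten(v)
    else:
        yield obj
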