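"""Glue between the similarity kernels and the network/model stages.

The sequence and DAG-semantic similarities do not depend on the
association matrix, so they are computed once per dataset
(:func:`static_similarities`); the GIP kernels, the fusions and the
heterogeneous network depend on the (possibly fold-masked) association
matrix and are recomputed per training fold (:func:`fold_matrices`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .data_io import AssociationTable, HyperParams
from .heterograph import apply_penalty, assemble_hetero, symmetric_normalize
from .similarity import (
    DiseaseDAG,
    availability_mask,
    fuse_similarity,
    gip_kernel,
    pirna_sequence_similarity,
    semantic_similarity_matrix,
)

__all__ = ["SimilarityBundle", "static_similarities", "fold_matrices"]


@dataclass
class SimilarityBundle:
    """Fold-independent similarity blocks.

    ``SP``/``SD`` carry meaningful values only where the corresponding
    mask is True (both entities have sequence / DAG evidence); the GIP
    kernel fills the rest at fusion time.
    """

    SP: np.ndarray
    sp_mask: np.ndarray
    SD: np.ndarray
    sd_mask: np.ndarray


def static_similarities(
    table: AssociationTable,
    sequences: Mapping[str, str] | None,
    dag: DiseaseDAG | None,
    hp: HyperParams,
) -> SimilarityBundle:
    """Sequence and semantic similarity blocks with availability masks.

    piRNAs missing from the FASTA and diseases missing from the DAG are
    kept in the vocabulary; their pairs fall back to the GIP kernel.
    """
    m, n = table.M, table.N

    sp = np.zeros((m, m))
    if sequences:
        have = [pid in sequences for pid in table.pirna_ids]
        idx = [i for i, ok in enumerate(have) if ok]
        if idx:
            sub = pirna_sequence_similarity(
                [sequences[table.pirna_ids[i]] for i in idx],
                hp.nw_match,
                hp.nw_mismatch,
                hp.nw_gap,
            )
            sp[np.ix_(idx, idx)] = sub
        sp_mask = availability_mask(have)
    else:
        sp_mask = np.zeros((m, m), dtype=bool)

    sd = np.zeros((n, n))
    if dag is not None:
        have_d = [did in dag for did in table.disease_ids]
        idx_d = [j for j, ok in enumerate(have_d) if ok]
        if idx_d:
            sub = semantic_similarity_matrix(
                dag,
                [table.disease_ids[j] for j in idx_d],
                hp.contribution_factor,
            )
            sd[np.ix_(idx_d, idx_d)] = sub
        sd_mask = availability_mask(have_d)
    else:
        sd_mask = np.zeros((n, n), dtype=bool)

    return SimilarityBundle(sp, sp_mask, sd, sd_mask)


def fold_matrices(
    A_train: np.ndarray, bundle: SimilarityBundle, hp: HyperParams
) -> dict[str, np.ndarray]:
    """All association-dependent matrices for one training fold.

    Recomputed from the masked training matrix so held-out positives
    can never leak through the GIP kernels or the network blocks.
    """
    A_train = np.asarray(A_train, dtype=float)
    m = A_train.shape[0]
    g_p = gip_kernel(A_train, "pirna")
    g_d = gip_kernel(A_train, "disease")
    spg = fuse_similarity(bundle.SP, g_p, bundle.sp_mask)
    sdg = fuse_similarity(bundle.SD, g_d, bundle.sd_mask)
    nspg = symmetric_normalize(spg)
    nsdg = symmetric_normalize(sdg)
    a_h = assemble_hetero(nspg, nsdg, A_train)
    b = apply_penalty(a_h, hp.penalty, m)
    return {
        "G_p": g_p,
        "G_d": g_d,
        "SPG": spg,
        "SDG": sdg,
        "NSPG": nspg,
        "NSDG": nsdg,
        "A_H": a_h,
        "B": b,
    }
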