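"""Similarity kernels against independent oracles and hand-computed values."""

import numpy as np
import pytest

from etgpda.similarity import (
    DegenerateMatrixWarning,
    DiseaseDAG,
    availability_mask,
    dag_contributions,
    fuse_similarity,
    gip_kernel,
    minmax_standardize,
    nw_score,
    pirna_sequence_similarity,
    semantic_similarity,
    semantic_similarity_matrix,
)

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_force_alignment_max(a, b, match, mismatch, gap):
    """Max score over an explicit enumeration of every global alignment."""

    def rec(i, j):
        if i == len(a) and j == len(b):
            return 0.0
        best = -np.inf
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            best = max(best, s + rec(i + 1, j + 1))
        if i < len(a):
            best = max(best, gap + rec(i + 1, j))
        if j < len(b):
            best = max(best, gap + rec(i, j + 1))
        return best

    return rec(0, 0)


def oracle_semantic(edges, d_a, d_b, delta):
    """Semantic similarity via explicit-stack DFS closures and exhaustive
    path enumeration (max of delta^len over all upward paths)."""
    parents = {}
    for c, p in edges:
        parents.setdefault(c, []).append(p)
        parents.setdefault(p, [])

    def closure(d):
        seen, stack = set(), [d]
        while stack:
            n = stack.pop()
            if n in seen:
                continue
            seen.add(n)
            stack.extend(parents.get(n, []))
        return seen

    def dv(d):
        out = {}

        def paths(node, depth):
            out[node] = max(out.get(node, 0.0), delta**depth)
            for p in parents.get(node, []):
                paths(p, depth + 1)

        paths(d, 0)
        return out

    if d_a == d_b:
        return 1.0
    dva, dvb = dv(d_a), dv(d_b)
    common = closure(d_a) & closure(d_b)
    if not common:
        return 0.0
    return sum(dva[t] + dvb[t] for t in common) / (
        sum(dva.values()) + sum(dvb.values())
    )


def random_dag_edges(rng, n_nodes):
    """Random acyclic child->parent edges: node i may only point at j < i."""
    edges = []
    for i in range(1, n_nodes):
        for j in range(i):
            if rng.random() < 0.3:
                edges.append((f"n{i}", f"n{j}"))
    # keep every node attached to the graph object
    edges.append(("n0", "root"))
    for i in range(1, n_nodes):
        if not any(c == f"n{i}" for c, _ in edges):
            edges.append((f"n{i}", "root"))
    return edges


# ---------------------------------------------------------------------------
# sequence alignment
# ---------------------------------------------------------------------------

class TestNeedlemanWunsch:
    @pytest.mark.parametrize(
        "a,b,expected",
        [("ACGT", "ACGT", 4.0), ("A", "T", -1.0), ("ACGT", "AGT", 2.0)],
    )
    def test_hand_examples(self, a, b, expected):
        assert nw_score(a, b, 1, -1, -1) == expected

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            nw_score("", "ACGT")

    def test_matches_exhaustive_enumeration(self, rng):
        """>=200 random short pairs against the alignment enumerator."""
        bases = np.array(list("ACGT"))
        for _ in range(200):
            la, lb = rng.integers(1, 8, size=2)
            a = "".join(rng.choice(bases, la))
            b = "".join(rng.choice(bases, lb))
            match, mismatch, gap = 1.0, -1.0, -1.0
            assert nw_score(a, b, match, mismatch, gap) == pytest.approx(
                brute_force_alignment_max(a, b, match, mismatch, gap), abs=1e-9
            )


class TestStandardize:
    def test_forced_by_formula(self):
        out = minmax_standardize(np.array([[2.0, 4.0], [6.0, 8.0]]))
        assert np.allclose(out, [[0, 1 / 3], [2 / 3, 1]])

    def test_constant_matrix_degenerates_to_zeros(self):
        with pytest.warns(DegenerateMatrixWarning):
            out = minmax_standardize(np.full((3, 3), 5.0))
        assert np.all(out == 0)

    def test_output_spans_unit_interval(self, rng):
        out = minmax_standardize(rng.normal(size=(6, 6)))
        assert out.min() == 0.0 and out.max() == 1.0


class TestSequenceSimilarityMatrix:
    def test_unit_diagonal(self, rng):
        seqs = ["ACGTACGT", "TTTTACGT", "ACGGGGTA"]
        sp = pirna_sequence_similarity(seqs)
        assert np.allclose(np.diag(sp), 1.0)
        assert np.allclose(sp, sp.T)

    def test_identical_pair_attains_matrix_maximum(self):
        # equal lengths: the duplicate pair's raw score equals every
        # self-alignment, so it standardizes to the matrix maximum
        seqs = ["ACGTACGT", "ACGTACGT", "TTTTCCCC", "GGGGAAAA"]
        sp = pirna_sequence_similarity(seqs)
        off = sp.copy()
        np.fill_diagonal(off, -np.inf)
        assert sp[0, 1] == off.max()

    def test_single_sequence(self):
        assert pirna_sequence_similarity(["ACGT"]).tolist() == [[1.0]]


# ---------------------------------------------------------------------------
# GIP kernel
# ---------------------------------------------------------------------------

class TestGip:
    def test_identical_profiles_score_one(self):
        A = np.array([[1, 0, 1], [1, 0, 1], [0, 1, 0]])
        g = gip_kernel(A, "pirna")
        assert g[0, 1] == pytest.approx(1.0)

    def test_hand_evaluation(self):
        A = np.array([[1, 0], [0, 1]])
        g = gip_kernel(A, "pirna")
        # phi = 1 / ((1 + 1) / 2) = 1; ||V1 - V2||^2 = 2
        assert g[0, 1] == pytest.approx(np.exp(-2.0))

    def test_symmetric_unit_diagonal(self, rng):
        A = (rng.random((7, 4)) < 0.4).astype(float)
        A[0, 0] = 1
        for axis in ("pirna", "disease"):
            g = gip_kernel(A, axis)
            assert np.allclose(g, g.T, atol=1e-12)
            assert np.allclose(np.diag(g), 1.0)
            assert g.min() >= 0 and g.max() <= 1

    def test_permutation_equivariance(self, rng):
        A = (rng.random((6, 5)) < 0.5).astype(float)
        A[0, 0] = 1
        perm = rng.permutation(6)
        g = gip_kernel(A, "pirna")
        g_perm = gip_kernel(A[perm], "pirna")
        assert np.allclose(g_perm, g[np.ix_(perm, perm)], atol=1e-12)

    def test_all_zero_profiles_rejected(self):
        with pytest.raises(ValueError):
            gip_kernel(np.zeros((3, 3)), "pirna")


# ---------------------------------------------------------------------------
# DAG semantics
# ---------------------------------------------------------------------------

class TestDagContributions:
    def test_root_only_disease(self):
        dag = DiseaseDAG(edges=[], nodes=["d"])
        assert dag_contributions(dag, "d", 0.5) == {"d": 1.0}

    def test_single_parent_decay(self):
        dag = DiseaseDAG([("d", "p")])
        assert dag_contributions(dag, "d", 0.5) == {"d": 1.0, "p": 0.5}

    def test_diamond_takes_max_over_paths(self):
        # d -> a -> r and d -> r: r reachable in 1 or 2 hops
        dag = DiseaseDAG([("d", "a"), ("a", "r"), ("d", "r")])
        dv = dag_contributions(dag, "d", 0.5)
        assert dv["r"] == pytest.approx(max(0.5, 0.25))

    def test_absent_disease_rejected(self):
        dag = DiseaseDAG([("d", "r")])
        with pytest.raises(KeyError):
            dag_contributions(dag, "zzz", 0.5)


class TestSemanticSimilarity:
    def test_self_similarity_is_one(self):
        dag = DiseaseDAG([("d", "r")])
        assert semantic_similarity(dag, "d", "d", 0.5) == 1.0

    def test_disjoint_dags_score_zero(self):
        dag = DiseaseDAG([("d1", "r1"), ("d2", "r2")])
        assert semantic_similarity(dag, "d1", "d2", 0.5) == 0.0

    def test_siblings_under_root(self):
        dag = DiseaseDAG([("d1", "r"), ("d2", "r")])
        # DV sums 1.5 each; shared node r contributes 0.5 + 0.5
        assert semantic_similarity(dag, "d1", "d2", 0.5) == pytest.approx(1 / 3)

    def test_matches_path_enumeration_oracle(self, rng):
        """>=100 random DAGs of <= 12 nodes against the exhaustive oracle."""
        for _ in range(100):
            n = int(rng.integers(2, 12))
            edges = random_dag_edges(rng, n)
            dag = DiseaseDAG(edges)
            names = dag.node_list
            d_a, d_b = rng.choice(len(names), size=2, replace=False)
            got = semantic_similarity(dag, names[d_a], names[d_b], 0.5)
            want = oracle_semantic(edges, names[d_a], names[d_b], 0.5)
            assert got == pytest.approx(want, abs=1e-9)

    def test_matrix_symmetric_unit_diag(self, rng):
        edges = random_dag_edges(rng, 8)
        dag = DiseaseDAG(edges)
        ids = dag.node_list[:5]
        sd = semantic_similarity_matrix(dag, ids, 0.5)
        assert np.allclose(sd, sd.T)
        assert np.allclose(np.diag(sd), 1.0)
        assert sd.min() >= 0 and sd.max() <= 1


# ---------------------------------------------------------------------------
# fusion
# ---------------------------------------------------------------------------

class TestFusion:
    def test_all_true_mask_selects_primary(self, rng):
        p, g = rng.random((4, 4)), rng.random((4, 4))
        out = fuse_similarity(p, g, np.ones((4, 4), bool))
        off = ~np.eye(4, dtype=bool)
        assert np.array_equal(out[off], p[off])
        assert np.allclose(np.diag(out), 1.0)

    def test_all_false_mask_selects_gip(self, rng):
        p, g = rng.random((4, 4)), rng.random((4, 4))
        out = fuse_similarity(p, g, np.zeros((4, 4), bool))
        off = ~np.eye(4, dtype=bool)
        assert np.array_equal(out[off], g[off])

    def test_mixed_mask_elementwise(self, rng):
        p, g = rng.random((3, 3)), rng.random((3, 3))
        avail = [True, False, True]
        mask = availability_mask(avail)
        out = fuse_similarity(p, g, mask)
        for i in range(3):
            for j in range(3):
                if i == j:
                    assert out[i, j] == 1.0
                elif avail[i] and avail[j]:
                    assert out[i, j] == p[i, j]
                else:
                    assert out[i, j] == g[i, j]

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fuse_similarity(np.eye(3), np.eye(4), np.ones((3, 3), bool))


def test_all_similarity_matrices_well_formed(small_world):
    """Symmetric within 1e-9, entries in [0,1], unit diagonal."""
    from etgpda.data_io import HyperParams
    from etgpda.pipeline import fold_matrices, static_similarities

    hp = HyperParams()
    w = small_world
    bundle = static_similarities(w.table, w.sequences, w.dag, hp)
    mats = fold_matrices(w.table.A.astype(float), bundle, hp)
    for name in ("G_p", "G_d", "SPG", "SDG"):
        m = mats[name]
        assert np.allclose(m, m.T, atol=1e-9), name
        assert m.min() >= 0 and m.max() <= 1, name
        assert np.allclose(np.diag(m), 1.0), name
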