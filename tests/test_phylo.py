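import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from pksnrps._seqgen import mutate, random_protein
from pksnrps.errors import ParseError, ValidationError
from pksnrps.io import ProteinRecord, write_fasta
from pksnrps.phylo import (CladePlacement, DistanceMatrix, assign_major_clade,
                           build_distance_matrix, parse_newick, to_newick,
                           upgma)


# ---------------------------------------------------------------------------
# independent brute-force UPGMA oracle: cluster means recomputed from the
# original matrix at every step, same tie rule as the implementation
# ---------------------------------------------------------------------------

def brute_force_upgma_heights(ids, d):
    clusters = [frozenset([i]) for i in range(len(ids))]
    heights = []
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                pairs = [(a, b) for a in clusters[i] for b in clusters[j]]
                mean = sum(d[a][b] for a, b in pairs) / len(pairs)
                key_i = min(ids[k] for k in clusters[i])
                key_j = min(ids[k] for k in clusters[j])
                ka, kb = sorted((key_i, key_j))
                cand = (mean, ka, kb, i, j)
                if best is None or cand[:3] < best[:3]:
                    best = cand
        mean, _, _, i, j = best
        heights.append(mean / 2)
        merged = clusters[i] | clusters[j]
        merges.append(frozenset(ids[k] for k in merged))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return heights, merges


def tree_merge_sets(tree):
    """(leafset, height) for every internal node, sorted by height."""
    out = []
    depths = tree.root_to_tip_depths()
    total = max(depths.values())

    def walk(node, acc):
        acc += node.length or 0.0
        if node.is_tip():
            return frozenset([node.name])
        leaves = frozenset()
        for ch in node.children:
            leaves |= walk(ch, acc)
        out.append((leaves, total - acc))
        return leaves

    walk(tree.root, 0.0)
    return sorted(out, key=lambda t: (t[1], sorted(t[0])))


def random_distance_matrix(rng, n):
    m = rng.uniform(0.05, 1.0, size=(n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    ids = [f"L{i}" for i in range(n)]
    return DistanceMatrix(ids=ids, d=m)


class TestUpgma:
    def test_hand_worked_three_leaf_example(self):
        # d(A,B)=2, d(A,C)=d(B,C)=8 -> ((A:1,B:1):3,C:4)
        m = DistanceMatrix(ids=["A", "B", "C"],
                           d=np.array([[0, 2, 8], [2, 0, 8], [8, 8, 0.0]]))
        tree = upgma(m)
        assert to_newick(tree) == "((A:1.000000,B:1.000000):3.000000,C:4.000000);"
        assert tree.is_ultrametric()

    def test_two_leaves_make_equal_cherry(self):
        m = DistanceMatrix(ids=["A", "B"], d=np.array([[0, 3.0], [3.0, 0]]))
        tree = upgma(m)
        depths = tree.root_to_tip_depths()
        assert depths == {"A": 1.5, "B": 1.5}

    def test_nan_rejected(self):
        m = DistanceMatrix(ids=["A", "B"], d=np.zeros((2, 2)))
        m.d[0, 1] = m.d[1, 0] = np.nan
        with pytest.raises(ValidationError):
            upgma(m)

    @pytest.mark.parametrize("n", [3, 4, 5, 6, 7])
    def test_agrees_with_bruteforce_oracle(self, n):
        rng = np.random.default_rng(1000 + n)
        for rep in range(8):
            m = random_distance_matrix(rng, n)
            tree = upgma(m)
            oracle_heights, oracle_merges = brute_force_upgma_heights(
                m.ids, m.d)
            got = tree_merge_sets(tree)
            assert len(got) == len(oracle_heights)
            # compare merge sets with their heights
            oracle = sorted(
                [(m_, h) for h, m_ in zip(oracle_heights, oracle_merges)],
                key=lambda t: (t[1], sorted(t[0])))
            for (leaves_a, h_a), (leaves_b, h_b) in zip(got, oracle,
                                                        strict=True):
                assert leaves_a == leaves_b
                assert h_a == pytest.approx(h_b, abs=1e-9)

    def test_agrees_with_scipy_average_linkage(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            m = random_distance_matrix(rng, 9)
            tree = upgma(m)
            ours = sorted(h for _, h in tree_merge_sets(tree))
            Z = linkage(squareform(m.d), method="average")
            theirs = sorted(Z[:, 2] / 2)
            assert np.allclose(ours, theirs, atol=1e-9)

    def test_ultrametric_for_random_inputs(self):
        rng = np.random.default_rng(11)
        for n in (3, 5, 8, 12):
            tree = upgma(random_distance_matrix(rng, n))
            assert tree.is_ultrametric(tol=1e-9)

    def test_recovers_ultrametric_matrix_exactly(self):
        # matrix induced by a random ultrametric tree is reproduced by the
        # output tree's path distances
        rng = np.random.default_rng(42)
        n = 6
        ids = [f"L{i}" for i in range(n)]
        # random agglomeration with increasing heights
        clusters = [{i} for i in range(n)]
        heights = {}
        level = 0.0
        while len(clusters) > 1:
            level += rng.uniform(0.05, 0.3)
            i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
            merged = clusters[i] | clusters[j]
            for a in clusters[i]:
                for b in clusters[j]:
                    heights[(min(a, b), max(a, b))] = level
            clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
            clusters.append(merged)
        d = np.zeros((n, n))
        for (a, b), h in heights.items():
            d[a, b] = d[b, a] = 2 * h
        tree = upgma(DistanceMatrix(ids=ids, d=d))
        names, dmat = tree.tip_distances()
        idx = {nm: k for k, nm in enumerate(names)}
        for a in range(n):
            for b in range(n):
                assert dmat[idx[ids[a]], idx[ids[b]]] == \
                    pytest.approx(d[a, b], abs=1e-9)


class TestDistanceMatrix:
    def test_identical_pair_zero_matrix(self):
        recs = [ProteinRecord(id="a", sequence="MKVLAW"),
                ProteinRecord(id="b", sequence="MKVLAW")]
        m = build_distance_matrix(recs)
        assert m.d[0, 1] == 0.0

    def test_ordering_forced_by_divergence(self):
        rng = np.random.default_rng(2)
        base = random_protein(rng, 200)
        far = random_protein(rng, 200)
        recs = [ProteinRecord(id="a", sequence=base),
                ProteinRecord(id="b", sequence=base),
                ProteinRecord(id="c", sequence=far)]
        m = build_distance_matrix(recs)
        assert m.d[0, 1] == 0.0
        assert m.d[0, 2] > 0.3
        assert m.d[0, 2] == pytest.approx(m.d[1, 2])

    def test_fewer_than_two_records_rejected(self):
        with pytest.raises(ValidationError):
            build_distance_matrix([ProteinRecord(id="a", sequence="MK")])

    def test_pairwise_equals_msa_on_gapless_alignment(self, tmp_path):
        rng = np.random.default_rng(3)
        base = random_protein(rng, 150)
        recs = [ProteinRecord(id="a", sequence=base),
                ProteinRecord(id="b", sequence=mutate(base, 0.05, rng)),
                ProteinRecord(id="c", sequence=mutate(base, 0.10, rng))]
        aln = tmp_path / "aln.faa"
        write_fasta(recs, aln)  # already equal-length and gapless
        m1 = build_distance_matrix(recs, mode="pairwise")
        m2 = build_distance_matrix(recs, mode="msa", alignment_path=aln)
        assert np.allclose(m1.d, m2.d)

    def test_unequal_msa_rows_rejected(self, tmp_path):
        recs = [ProteinRecord(id="a", sequence="MKVLAW"),
                ProteinRecord(id="b", sequence="MKV")]
        aln = tmp_path / "bad.faa"
        write_fasta(recs, aln)
        with pytest.raises(ValidationError, match="unequal"):
            build_distance_matrix(recs, mode="msa", alignment_path=aln)


class TestNewick:
    def test_parse_three_leaf_tree(self):
        tree = parse_newick("((A:1,B:1):3,C:4);")
        assert sorted(tree.leaf_names()) == ["A", "B", "C"]
        children = {tuple(sorted(t.name for t in ch.tips())) if not
                    ch.is_tip() else (ch.name,)
                    for ch in tree.root.children}
        assert children == {("A", "B"), ("C",)}

    def test_roundtrip_preserves_everything(self):
        m = DistanceMatrix(ids=["A", "B", "C"],
                           d=np.array([[0, 2, 8], [2, 0, 8], [8, 8, 0.0]]))
        tree = upgma(m)
        text = to_newick(tree)
        back = parse_newick(text)
        assert to_newick(back) == text
        assert sorted(back.leaf_names()) == sorted(tree.leaf_names())

    def test_unbalanced_parentheses_rejected_with_position(self):
        with pytest.raises(ParseError, match="unbalanced"):
            parse_newick("((A:1,B:1")
        with pytest.raises(ParseError, match="position"):
            parse_newick("(A:1,B:1));")


class TestAssignMajorClade:
    def _tree(self):
        # two reference cherries per side plus an outgroup-like leaf
        return parse_newick(
            "((((q1:1,refIa:1):1,refIb:2):2,(q2:2.5,refII:2.5):1.5):4,"
            "(refIII:3,(out1:1,q3:1):2):5);")

    def _refs(self):
        return {"refIa": "Ia", "refIb": "Ib", "refII": "II", "refIII": "III"}

    def test_nearest_reference_wins(self):
        placements = assign_major_clade(self._tree(), self._refs(),
                                        outgroups=["out1"])
        assert placements["q1"].major_clade == "Ia"
        assert placements["q2"].major_clade == "II"

    def test_nearest_outgroup_means_unplaced(self):
        placements = assign_major_clade(self._tree(), self._refs(),
                                        outgroups=["out1"])
        assert placements["q3"].major_clade == "unplaced"

    def test_references_are_not_queries(self):
        placements = assign_major_clade(self._tree(), self._refs(),
                                        outgroups=["out1"])
        assert set(placements) == {"q1", "q2", "q3"}

    def test_tie_breaks_to_smallest_reference_id(self):
        # refA and refB sit at the same path distance from q
        tree2 = parse_newick("(q:1,refA:2,refB:2,refC:3,refD:3);")
        placements2 = assign_major_clade(
            tree2, {"refA": "Ib", "refB": "Ia", "refC": "II", "refD": "III"},
            outgroups=[])
        assert placements2["q"].nearest_reference == "refA"
        assert placements2["q"].major_clade == "Ib"

    def test_missing_reference_clade_rejected(self):
        tree = parse_newick("((q:1,refA:1):1,refB:2);")
        with pytest.raises(ValidationError, match="III"):
            assign_major_clade(tree, {"refA": "Ia", "refB": "Ib"},
                               outgroups=[])
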