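"""Neighbor joining, bootstrap supports, cluster cutting, and anchored clade
extraction."""

import dendropy
import numpy as np
import pytest

from divkit import (
    AlignedSequenceSet,
    PopulationSimConfig,
    SequenceRecord,
    bootstrap_support,
    build_nj_tree,
    cut_into_clusters,
    extract_clades,
    mcl_distances,
    simulate_population_alleles,
)
from divkit.distance import DistanceMatrix


def _patristic(tree):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    return lambda a, b: pdm.distance(taxa[a], taxa[b])


class TestNeighborJoining:
    def test_additive_matrix_exact_recovery(self):
        """A matrix built from a known 4-taxon tree is reproduced exactly:
        same topology, same path lengths."""
        # tree: ((a:2,b:3):1,c:4,d:5) -> additive distances by hand
        d = {
            ("a", "b"): 5, ("a", "c"): 7, ("a", "d"): 8,
            ("b", "c"): 8, ("b", "d"): 9, ("c", "d"): 9,
        }
        labels = ["a", "b", "c", "d"]
        M = np.zeros((4, 4))
        for (x, y), v in d.items():
            i, j = labels.index(x), labels.index(y)
            M[i, j] = M[j, i] = v
        tree = build_nj_tree(DistanceMatrix(labels, M, np.zeros((4, 4))))
        dist = _patristic(tree)
        for (x, y), v in d.items():
            assert dist(x, y) == pytest.approx(v, abs=1e-9)
        # topology: (a,b) form a cherry
        ab = tree.mrca(taxon_labels=["a", "b"])
        assert {lf.taxon.label for lf in ab.leaf_iter()} == {"a", "b"}

    def test_three_taxa_closed_form(self):
        M = np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
        tree = build_nj_tree(DistanceMatrix(["x", "y", "z"], M, np.zeros((3, 3))))
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert lengths["x"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["y"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["z"] == pytest.approx((4 + 5 - 3) / 2)

    def test_agrees_with_skbio_on_random_matrix(self):
        """Cross-check topology against an independent NJ implementation."""
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(5)
        n = 8
        pts = rng.random((n, 3)) * 2
        M = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = [f"t{i}" for i in range(n)]
        ours = build_nj_tree(DistanceMatrix(labels, M, np.zeros((n, n))))
        theirs = skbio.tree.nj(skbio.DistanceMatrix(M, ids=labels))
        ours_bp = _bipartition_set(ours)
        theirs_nwk = theirs.__str__()
        theirs_tree = dendropy.Tree.get(data=theirs_nwk, schema="newick")
        assert ours_bp == _bipartition_set(theirs_tree)

    def test_nonfinite_distance_names_pair(self):
        M = np.zeros((3, 3))
        M[0, 1] = M[1, 0] = np.nan
        with pytest.raises(ValueError, match="t0.*t1|t1.*t0"):
            build_nj_tree(DistanceMatrix(["t0", "t1", "t2"], M, np.zeros((3, 3))))

    def test_negative_branch_clamped(self):
        M = np.array(
            [[0, 1, 5, 5], [1, 0, 5.2, 4.8], [5, 5.2, 0, 1], [5, 4.8, 1, 0]], dtype=float
        )
        tree = build_nj_tree(DistanceMatrix(list("abcd"), M, np.zeros((4, 4))))
        for e in tree.edges():
            if e.length is not None:
                assert e.length >= 0


def _bipartition_set(tree):
    labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    out = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 1 < len(side) < len(labels) - 1:
            out.add(min(side, frozenset(labels - side), key=sorted))
    return out


def _two_clan_alignment(seed=0):
    rng = np.random.default_rng(seed)
    base = rng.choice(list("ACGT"), size=900)

    def mutate(seq, rate):
        s = seq.copy()
        k = rng.binomial(len(s), rate)
        for i in rng.choice(len(s), size=k, replace=False):
            s[i] = rng.choice([c for c in "ACGT" if c != s[i]])
        return s

    clanA = mutate(base, 0.25)
    clanB = mutate(base, 0.25)
    recs = []
    for i in range(3):
        recs.append(SequenceRecord(f"A{i}", "".join(mutate(clanA, 0.01))))
        recs.append(SequenceRecord(f"B{i}", "".join(mutate(clanB, 0.01))))
    return AlignedSequenceSet(recs)


class TestBootstrap:
    def test_separated_clans_high_support(self):
        aln = _two_clan_alignment(seed=1)
        tree = bootstrap_support(aln, reps=100, seed=0)
        side = frozenset(["A0", "A1", "A2"])
        assert tree.bipartition_support.get(min(side, frozenset(["B0", "B1", "B2"]), key=sorted), 0) >= 99

    def test_identical_sequences_degenerate(self):
        recs = [SequenceRecord(f"s{i}", "ACGT" * 30) for i in range(4)]
        tree = bootstrap_support(AlignedSequenceSet(recs), reps=20, seed=0)
        assert tree.degenerate
        assert all((n.support in (None, 0.0)) for n in tree.preorder_node_iter())

    def test_seed_determinism(self):
        aln = _two_clan_alignment(seed=2)
        t1 = bootstrap_support(aln, reps=30, seed=7)
        t2 = bootstrap_support(aln, reps=30, seed=7)
        assert t1.bipartition_support == t2.bipartition_support

    def test_support_invariant_under_leaf_order(self):
        aln = _two_clan_alignment(seed=3)
        shuffled = AlignedSequenceSet(list(reversed(aln.records)))
        t1 = bootstrap_support(aln, reps=30, seed=5)
        t2 = bootstrap_support(shuffled, reps=30, seed=5)
        common = set(t1.bipartition_support) & set(t2.bipartition_support)
        assert common  # the deep split at least
        side = frozenset(["A0", "A1", "A2"])
        key = min(side, frozenset(["B0", "B1", "B2"]), key=sorted)
        assert t1.bipartition_support[key] == pytest.approx(t2.bipartition_support[key], abs=15)

    def test_rejects_zero_reps(self):
        with pytest.raises(ValueError):
            bootstrap_support(_two_clan_alignment(), reps=0)


class TestCladeExtraction:
    def test_cherry_anchor(self):
        tree = dendropy.Tree.get(data="((a:1,b:1):1,(c:1,d:1):1,e:2);", schema="newick")
        ca = extract_clades(tree, {"X": ["a", "b"]}, min_support=0)
        assert ca.members("X") == {"a", "b"}
        assert ca.assignment["e"] == "unassigned"

    def test_missing_anchor_raises(self):
        tree = dendropy.Tree.get(data="((a:1,b:1):1,c:1,d:2);", schema="newick")
        with pytest.raises(ValueError, match="ghost"):
            extract_clades(tree, {"X": ["ghost"]})

    def test_conflicting_anchors_raise(self):
        tree = dendropy.Tree.get(data="((a:1,b:1):1,(c:1,d:1):1,e:2);", schema="newick")
        with pytest.raises(ValueError, match="overlap"):
            extract_clades(tree, {"X": ["a", "b"], "Y": ["a", "c", "d", "b"]}, min_support=0)

    def test_planted_clusters_recovered(self):
        pop = simulate_population_alleles(PopulationSimConfig(seed=3))
        tree = bootstrap_support(pop.alleles, reps=40, seed=1)
        by_locus = {}
        for a, l in pop.locus_of.items():
            by_locus.setdefault(l, []).append(a)
        anchors = {l: sorted(mem)[:2] for l, mem in by_locus.items() if len(mem) >= 2}
        ca = extract_clades(tree, anchors, min_support=70)
        for l, mem in by_locus.items():
            if l in anchors:
                assert ca.members(l) == set(mem)

    def test_assignment_partitions_leaves(self):
        pop = simulate_population_alleles(PopulationSimConfig(seed=6))
        tree = bootstrap_support(pop.alleles, reps=30, seed=2)
        some = sorted(pop.locus_of)[:2]
        ca = extract_clades(tree, {"X": some}, min_support=50)
        assert set(ca.assignment) == set(pop.genotype.columns)


class TestClusterCutting:
    def test_planted_loci_recovered_as_clusters(self):
        pop = simulate_population_alleles(PopulationSimConfig(seed=12))
        dm = mcl_distances(pop.alleles, bootstrap_reps=0)
        tree = build_nj_tree(dm)
        k = len(set(pop.locus_of.values()))
        clusters = cut_into_clusters(tree, k)
        truth = {}
        for a, l in pop.locus_of.items():
            truth.setdefault(l, set()).add(a)
        assert sorted(map(sorted, clusters)) == sorted(map(sorted, truth.values()))

    def test_k1_is_everything(self):
        tree = dendropy.Tree.get(data="((a:1,b:1):1,(c:1,d:1):1,e:2);", schema="newick")
        assert cut_into_clusters(tree, 1) == [{"a", "b", "c", "d", "e"}]
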