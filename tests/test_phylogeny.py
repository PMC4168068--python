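import random

import numpy as np
import pytest
from skbio import TreeNode

from phamkit.phams import PhamPartition
from phamkit.phylogeny import (
    COS_3PRIME,
    HEADFUL,
    UNDETERMINED,
    DistanceMatrix,
    PackagingConflictError,
    infer_packaging,
    neighbor_joining,
    terminase_distances,
    tree_to_newick,
)
from phamkit.similarity import align_proteins

from conftest import mutate_peptide, random_peptide


def random_additive_tree(rng: random.Random, n: int) -> TreeNode:
    nodes = [TreeNode(name=f"T{i}") for i in range(n)]
    for nd in nodes:
        nd.length = round(rng.uniform(0.05, 1.0), 4)
    while len(nodes) > 2:
        i, j = sorted(rng.sample(range(len(nodes)), 2), reverse=True)
        a, b = nodes.pop(i), nodes.pop(j)
        parent = TreeNode()
        parent.length = round(rng.uniform(0.05, 1.0), 4)
        parent.extend([a, b])
        nodes.append(parent)
    root = TreeNode()
    root.extend(nodes)
    return root


class TestDistances:
    def test_identical_proteins_have_zero_distance(self):
        rng = random.Random(30)
        s = random_peptide(rng, 50)
        m = terminase_distances([("a", s), ("b", s), ("c", s)])
        assert np.allclose(m.d, 0.0)

    def test_dissimilar_peptides_near_one(self):
        m = terminase_distances(
            [("a", "WWWWWWWWWW"), ("b", "KKKKKKKKKK"), ("c", "DDDDDDDDDD")]
        )
        off = m.d[np.triu_indices(3, 1)]
        assert (off > 0.9).all()

    def test_matches_align_proteins_recomputation(self):
        rng = random.Random(31)
        base = random_peptide(rng, 60)
        prots = [
            ("a", base),
            ("b", mutate_peptide(rng, base, 0.2)),
            ("c", random_peptide(rng, 55)),
        ]
        m = terminase_distances(prots)
        for i in range(3):
            for j in range(i + 1, 3):
                r = align_proteins(prots[i][1], prots[j][1])
                assert m.d[i, j] == pytest.approx(1 - r.percent_identity / 100)

    def test_needs_three_taxa(self):
        with pytest.raises(ValueError):
            terminase_distances([("a", "MKV"), ("b", "MKV")])


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        m = DistanceMatrix(("A", "B", "C"), np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float))
        tree = neighbor_joining(m)
        lengths = {n.name: n.length for n in tree.children}
        assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}

    @pytest.mark.parametrize("trial", range(25))
    def test_recovers_random_additive_trees_exactly(self, trial):
        rng = random.Random(100 + trial)
        n = rng.randint(4, 8)
        source = random_additive_tree(rng, n)
        dm = source.tip_tip_distances()
        taxa = tuple(str(t) for t in dm.ids)
        nj = neighbor_joining(DistanceMatrix(taxa, dm.data))
        got = nj.tip_tip_distances(endpoints=list(taxa))
        assert np.allclose(got.filter(taxa).data, dm.filter(taxa).data, atol=1e-9)

    def test_star_matrix_gives_zero_internal_branches(self):
        m = DistanceMatrix(
            ("A", "B", "C", "D"), np.full((4, 4), 2.0) - 2 * np.eye(4)
        )
        tree = neighbor_joining(m)
        internal = [
            n.length for n in tree.traverse() if not n.is_tip() and n.length is not None
        ]
        assert all(abs(x) < 1e-12 for x in internal)
        assert all(n.length == pytest.approx(1.0) for n in tree.tips())

    def test_input_order_invariance_up_to_isomorphism(self):
        rng = random.Random(32)
        source = random_additive_tree(rng, 6)
        dm = source.tip_tip_distances()
        taxa = tuple(str(t) for t in dm.ids)
        t1 = neighbor_joining(DistanceMatrix(taxa, dm.data))
        perm = list(range(len(taxa)))
        rng.shuffle(perm)
        taxa2 = tuple(taxa[i] for i in perm)
        t2 = neighbor_joining(
            DistanceMatrix(taxa2, dm.data[np.ix_(perm, perm)])
        )
        d1 = t1.tip_tip_distances(endpoints=list(taxa)).filter(taxa)
        d2 = t2.tip_tip_distances(endpoints=list(taxa)).filter(taxa)
        assert np.allclose(d1.data, d2.data, atol=1e-9)

    def test_branch_lengths_never_negative(self):
        rng = random.Random(33)
        for _ in range(20):
            n = rng.randint(3, 7)
            d = np.abs(rng.random() + np.random.default_rng(rng.randint(0, 10**6)).random((n, n)))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0.0)
            tree = neighbor_joining(DistanceMatrix(tuple(f"t{i}" for i in range(n)), d))
            assert all(
                (node.length is None) or (node.length >= 0) for node in tree.traverse()
            )

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(("a", "b", "c"), np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0]], float))

    def test_newick_serialization(self):
        m = DistanceMatrix(("A", "B", "C"), np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float))
        nwk = tree_to_newick(neighbor_joining(m))
        assert nwk.endswith(";")
        assert "A:1.0" in nwk and "C:3.0" in nwk


def _partition(member_sets):
    pham_of = {}
    members = {}
    for pid, mem in enumerate(member_sets, start=1):
        members[pid] = frozenset(mem)
        for g in mem:
            pham_of[g] = pid
    return PhamPartition(pham_of, members)


class TestInferPackaging:
    def test_headful_transferred_from_characterized_pham_mates(self):
        p = _partition([{"Jimmer1_gp2", "P40_gp2", "SPP1_gp1"}])
        calls = infer_packaging(
            p,
            {"Jimmer1": "Jimmer1_gp2", "P40": "P40_gp2", "SPP1": "SPP1_gp1"},
            {"P40": HEADFUL, "SPP1": HEADFUL},
        )
        by_phage = {c.phage: c for c in calls}
        assert by_phage["Jimmer1"].strategy == HEADFUL
        assert by_phage["Jimmer1"].evidence in ("P40", "SPP1")

    def test_cohesive_ends_case(self):
        p = _partition([{"Pl23_gp2", "phiSLT_gp39"}])
        calls = infer_packaging(
            p,
            {"Pl23": "Pl23_gp2", "phiSLT": "phiSLT_gp39"},
            {"phiSLT": COS_3PRIME},
        )
        assert {c.strategy for c in calls if c.phage == "Pl23"} == {COS_3PRIME}

    def test_orpham_terminase_stays_undetermined(self):
        p = _partition([{"Emery_gp3"}, {"X_gp1", "Y_gp1"}])
        calls = infer_packaging(
            p,
            {"Emery": "Emery_gp3", "X": "X_gp1", "Y": "Y_gp1"},
            {"X": HEADFUL},
        )
        emery = next(c for c in calls if c.phage == "Emery")
        assert emery.strategy == UNDETERMINED
        assert emery.evidence == "orpham"

    def test_conflicting_pham_raises(self):
        p = _partition([{"A_gp1", "B_gp1", "C_gp1"}])
        with pytest.raises(PackagingConflictError):
            infer_packaging(
                p,
                {"A": "A_gp1", "B": "B_gp1", "C": "C_gp1"},
                {"B": HEADFUL, "C": COS_3PRIME},
            )

    def test_no_determinate_call_without_characterized_mate(self):
        p = _partition([{"A_gp1", "B_gp1"}])
        calls = infer_packaging(p, {"A": "A_gp1", "B": "B_gp1"}, {})
        assert all(c.strategy == UNDETERMINED for c in calls)
        determinate = [c for c in calls if c.strategy != UNDETERMINED]
        assert all(c.evidence not in ("orpham", "") for c in determinate)
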