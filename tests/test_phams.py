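import itertools
import random

import pytest

from phamkit.genome_io import FORWARD, Genome, Gene
from phamkit.phams import (
    PhamPartition,
    PhamThresholds,
    SimilarityEdge,
    build_similarity_graph,
    cluster_phams,
    pham_circle,
    pham_domain_coverage,
    pham_summary,
    remove_genome_recount,
    shared_pham_table,
    summary_from_counts,
)

from _oracles import components, gotoh_local_score, karlin_altschul_evalue
from conftest import cds_for_peptide, make_genome, mutate_peptide, random_peptide


def edge(a, b, passes):
    ev = 1e-60 if passes else 1.0
    return SimilarityEdge(a, b, evalue=ev, pct_identity=0.0, passes=passes)


class TestThresholds:
    def test_boundary_values_fail_both_cutoffs(self):
        t = PhamThresholds()
        assert t.passes(1e-50, 32.5) is False
        assert t.passes(9.99e-51, 0.0) is True
        assert t.passes(1.0, 32.51) is True

    def test_identical_proteins_pass(self):
        rng = random.Random(0)
        s = random_peptide(rng, 60)
        edges = build_similarity_graph([("a", s), ("b", s)])
        assert edges[0].passes
        assert edges[0].pct_identity == 100.0

    def test_duplicate_gene_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_similarity_graph([("a", "MKV"), ("a", "MKV")])


class TestBuildSimilarityGraph:
    def test_passes_set_matches_naive_recomputation(self):
        """Eight proteins in two families plus singletons: the passing
        pairs equal an oracle that recomputes both metrics naively
        (exhaustive local DP score -> E-value; positional identity)."""
        rng = random.Random(13)
        fam_a = random_peptide(rng, 45)
        fam_b = random_peptide(rng, 50)
        prots = [
            ("a1", fam_a),
            ("a2", mutate_peptide(rng, fam_a, 0.15)),
            ("a3", mutate_peptide(rng, fam_a, 0.20)),
            ("b1", fam_b),
            ("b2", mutate_peptide(rng, fam_b, 0.15)),
            ("s1", random_peptide(rng, 40)),
            ("s2", random_peptide(rng, 55)),
            ("s3", random_peptide(rng, 35)),
        ]
        t = PhamThresholds()
        got = {
            frozenset((e.protein_a, e.protein_b))
            for e in build_similarity_graph(prots, t)
            if e.passes
        }
        expected = set()
        for (ida, sa), (idb, sb) in itertools.combinations(prots, 2):
            ev = karlin_altschul_evalue(gotoh_local_score(sa, sb), len(sa), len(sb))
            if len(sa) == len(sb):
                ident = 100 * sum(x == y for x, y in zip(sa, sb)) / len(sa)
            else:
                ident = 0.0  # unrelated cross-length pairs in this fixture
            if ev < t.evalue_max or ident > t.identity_min_pct:
                expected.add(frozenset((ida, idb)))
        assert got == expected

    def test_all_pairs_emitted(self):
        rng = random.Random(14)
        prots = [(f"p{k}", random_peptide(rng, 20)) for k in range(6)]
        edges = build_similarity_graph(prots)
        assert len(edges) == 15  # n(n-1)/2


class TestClusterPhams:
    def test_single_linkage_chain(self):
        edges = [edge("A", "B", True), edge("B", "C", True), edge("A", "C", False)]
        p = cluster_phams(edges, ["A", "B", "C"])
        assert p.members[1] == frozenset({"A", "B", "C"})

    def test_no_passing_edges_gives_all_orphams(self):
        names = list("ABCDE")
        p = cluster_phams([edge(a, b, False) for a, b in itertools.combinations(names, 2)], names)
        assert len(p.members) == 5
        assert all(len(m) == 1 for m in p.members.values())

    def test_unknown_protein_in_edge_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            cluster_phams([edge("A", "Z", True)], ["A", "B"])

    @pytest.mark.parametrize("n_graphs", [1000])
    def test_matches_reachability_oracle_on_random_graphs(self, n_graphs):
        rng = random.Random(15)
        for _ in range(n_graphs):
            n = rng.randint(1, 12)
            nodes = [f"n{k}" for k in range(n)]
            edges = []
            chosen = []
            for a, b in itertools.combinations(nodes, 2):
                passes = rng.random() < 0.25
                edges.append(edge(a, b, passes))
                if passes:
                    chosen.append((a, b))
            p = cluster_phams(edges, nodes)
            assert set(p.members.values()) == components(nodes, chosen)

    def test_order_invariance_and_deterministic_ids(self):
        rng = random.Random(16)
        nodes = [f"n{k}" for k in range(10)]
        edges = [
            edge(a, b, rng.random() < 0.3) for a, b in itertools.combinations(nodes, 2)
        ]
        p1 = cluster_phams(edges, nodes)
        rng.shuffle(edges)
        p2 = cluster_phams(list(reversed(edges)), list(reversed(nodes)))
        assert p1 == p2

    def test_partition_covers_every_protein_once(self, small_cohort):
        genomes, _ = small_cohort
        prots = [(g2.gene_id, g2.aa_seq) for g in genomes for g2 in g.genes]
        p = cluster_phams(build_similarity_graph(prots), [x[0] for x in prots])
        assert sorted(p.pham_of) == sorted(x[0] for x in prots)
        assert sum(len(m) for m in p.members.values()) == len(prots)

    def test_relaxing_thresholds_never_increases_pham_count(self):
        rng = random.Random(17)
        prots = [(f"p{k}", random_peptide(rng, 30)) for k in range(8)]
        strict = PhamThresholds(evalue_max=1e-60, identity_min_pct=60.0)
        loose = PhamThresholds(evalue_max=1e-3, identity_min_pct=10.0)
        counts = []
        for t in (strict, loose):
            edges = build_similarity_graph(prots, t)
            counts.append(len(cluster_phams(edges, [x[0] for x in prots]).members))
        assert counts[1] <= counts[0]


class TestPhamSummary:
    def test_database_scale_arithmetic(self):
        s = summary_from_counts(13_697, 6_181, 2_233, 9_749)
        assert s.n_orphams == 3_948
        assert s.pct_multimember_phams == 36.1
        assert s.pct_orphams == 28.8
        # 9,749/13,697 = 71.176% -> 71.2 under half-up rounding
        assert s.pct_proteins_in_multimember == 71.2

    def test_all_orphams(self):
        p = cluster_phams([], ["a", "b", "c"])
        assert pham_summary(p).pct_orphams == 100.0

    def test_one_pham_holds_everything(self):
        edges = [edge("a", "b", True), edge("b", "c", True)]
        s = pham_summary(cluster_phams(edges, ["a", "b", "c"]))
        assert s.pct_multimember_phams == 100.0
        assert s.n_orphams == 0

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            summary_from_counts(100, 10, 5, 96)  # 10 != 5 + 4


def _cds_for(aa_count: int) -> str:
    return "ATG" + "GCA" * aa_count + "TAA"


def _three_genome_setup():
    cds = _cds_for(20)
    g1 = make_genome("PL_A", [(cds, FORWARD)] * 3)
    g2 = make_genome("PL_B", [(cds, FORWARD)] * 3)
    g3 = make_genome("OTHER", [(cds, FORWARD)] * 2)
    return [g1, g2, g3]


class TestSharedPhamTable:
    def test_planted_cross_host_classification(self):
        genomes = _three_genome_setup()
        # phams: {A1,B1,O1} cross-host, {A2,B2} focal-only, rest orphams
        pham_of = {
            "PL_A_gp1": 1, "PL_B_gp1": 1, "OTHER_gp1": 1,
            "PL_A_gp2": 2, "PL_B_gp2": 2,
            "PL_A_gp3": 3, "PL_B_gp3": 4, "OTHER_gp2": 5,
        }
        members = {}
        for gid, pid in pham_of.items():
            members.setdefault(pid, set()).add(gid)
        p = PhamPartition(pham_of, {k: frozenset(v) for k, v in members.items()})
        rows = {r.phage: r for r in shared_pham_table(p, genomes, {"PL_A", "PL_B"})}
        a = rows["PL_A"]
        assert (a.n_shared_with_other_hosts, a.n_focal_group_only, a.n_orphams) == (1, 1, 1)
        for r in rows.values():
            assert (
                r.n_shared_with_other_hosts + r.n_focal_group_only + r.n_orphams
                == r.n_genes
            )

    def test_single_genome_alone_has_no_outside_category(self):
        cds = _cds_for(15)
        g = make_genome("SOLO", [(cds, FORWARD)] * 4)
        prots = g.proteins()
        p = cluster_phams(build_similarity_graph(prots), [x[0] for x in prots])
        (row,) = shared_pham_table(p, [g], {"SOLO"})
        assert row.n_shared_with_other_hosts == 0
        assert row.n_focal_group_only + row.n_orphams == 4

    def test_missing_focal_phage_rejected(self):
        genomes = _three_genome_setup()
        p = cluster_phams([], [gene.gene_id for g in genomes for gene in g.genes])
        with pytest.raises(ValueError, match="absent"):
            shared_pham_table(p, genomes, {"NOPE"})


class TestRemoveGenomeRecount:
    def _twin_pair(self, n_shared=31):
        rng = random.Random(18)
        cds = [cds_for_peptide(random_peptide(rng, 30)) for _ in range(n_shared)]
        twin1 = make_genome("Twin1", [(c, FORWARD) for c in cds])
        twin2 = make_genome("Twin2", [(c, FORWARD) for c in cds])
        return twin1, twin2

    def test_twin_removal_creates_planted_orphams(self):
        twin1, twin2 = self._twin_pair(31)
        prots = twin1.proteins() + twin2.proteins()
        edges = build_similarity_graph(prots)
        _, newly = remove_genome_recount(edges, [twin1, twin2], "Twin2")
        assert len(newly) == 31
        assert all(gid.startswith("Twin1") for gid in newly)

    def test_equals_full_reclustering_without_victim(self, small_cohort):
        genomes, _ = small_cohort
        prots = [(g2.gene_id, g2.aa_seq) for g in genomes for g2 in g.genes]
        edges = build_similarity_graph(prots)
        victim = genomes[1].name
        after, _ = remove_genome_recount(edges, genomes, victim)
        kept = [
            (g2.gene_id, g2.aa_seq)
            for g in genomes
            if g.name != victim
            for g2 in g.genes
        ]
        scratch = cluster_phams(
            build_similarity_graph(kept), [x[0] for x in kept]
        )
        assert after == scratch

    def test_unknown_victim_rejected(self, small_cohort):
        genomes, _ = small_cohort
        with pytest.raises(ValueError, match="unknown"):
            remove_genome_recount([], genomes, "NotAPhage")


class TestPhamCircle:
    def _partition(self, k):
        gids = [f"ph{i:02d}_gp1" for i in range(k)]
        pham_of = {g: 1 for g in gids}
        return PhamPartition(pham_of, {1: frozenset(gids)}), {
            g: g.split("_")[0] for g in gids
        }

    @pytest.mark.parametrize("k", range(1, 11))
    def test_link_count_is_k_choose_2(self, k):
        p, phage_of = self._partition(k)
        circle = pham_circle(p, 1, sorted({v for v in phage_of.values()}), phage_of)
        assert len(circle.links) == k * (k - 1) // 2
        assert len(circle.entries) == k

    def test_sixteen_phage_antirepressor_scale(self):
        p, phage_of = self._partition(16)
        circle = pham_circle(p, 1, sorted({v for v in phage_of.values()}), phage_of)
        assert len(circle.entries) == 16
        assert len(circle.links) == 120

    def test_unknown_pham_rejected(self):
        p, phage_of = self._partition(2)
        with pytest.raises(ValueError):
            pham_circle(p, 99, [], phage_of)


class TestDomainCoverage:
    def _orpham_partition(self, n):
        gids = [f"g{k:05d}" for k in range(n)]
        return PhamPartition(
            {g: k + 1 for k, g in enumerate(gids)},
            {k + 1: frozenset([g]) for k, g in enumerate(gids)},
        ), gids

    def test_database_scale_fraction(self):
        p, gids = self._orpham_partition(6_181)
        domains = {g: ["pfam00001"] for g in gids[:1_501]}
        assert pham_domain_coverage(p, domains) == 24.3

    def test_empty_table(self):
        p, _ = self._orpham_partition(5)
        assert pham_domain_coverage(p, {}) == 0.0

    def test_everything_annotated(self):
        p, gids = self._orpham_partition(5)
        assert pham_domain_coverage(p, {g: ["d"] for g in gids}) == 100.0
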