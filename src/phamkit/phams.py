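"""Pham (protein phamily) clustering and its summary tables.

Proteins are grouped by single linkage: an edge between two proteins
passes when its E-value is *strictly* below the cutoff (default 1e-50) OR
its percent identity is *strictly* above the cutoff (default 32.5%), and a
pham is a connected component of the passing-edge graph. A protein with no
passing edge is an "orpham" (pham of size one). Boundary values fail both
tests by design.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from ._util import percent
from .genome_io import Genome
from .similarity import AlignmentResult, ScoringParams, align_proteins


@dataclass(frozen=True)
class PhamThresholds:
    evalue_max: float = 1e-50
    identity_min_pct: float = 32.5

    def __post_init__(self):
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be positive")
        if not (0 <= self.identity_min_pct <= 100):
            raise ValueError("identity_min_pct must lie in [0, 100]")

    def passes(self, evalue: float, pct_identity: float) -> bool:
        return evalue < self.evalue_max or pct_identity > self.identity_min_pct


@dataclass(frozen=True)
class SimilarityEdge:
    protein_a: str
    protein_b: str
    evalue: float
    pct_identity: float
    passes: bool


@dataclass(frozen=True)
class PhamPartition:
    pham_of: dict[str, int]
    members: dict[int, frozenset[str]]

    def __post_init__(self):
        for pid, mem in self.members.items():
            for g in mem:
                if self.pham_of.get(g) != pid:
                    raise ValueError(f"inconsistent partition at {g!r}")
        if len(self.pham_of) != sum(len(m) for m in self.members.values()):
            raise ValueError("partition maps are inconsistent")

    @property
    def n_proteins(self) -> int:
        return len(self.pham_of)

    def orphams(self) -> list[int]:
        return sorted(pid for pid, m in self.members.items() if len(m) == 1)


@dataclass(frozen=True)
class PhamSummary:
    n_proteins: int
    n_phams: int
    n_multimember_phams: int
    n_proteins_in_multimember: int
    n_orphams: int
    pct_multimember_phams: float
    pct_proteins_in_multimember: float
    pct_orphams: float


def build_similarity_graph(
    proteins: Sequence[tuple[str, str]],
    thresholds: PhamThresholds | None = None,
    params: ScoringParams | None = None,
) -> list[SimilarityEdge]:
    """All-vs-all comparison: one edge record per unordered pair."""
    thresholds = thresholds or PhamThresholds()
    params = params or ScoringParams()
    ids = [gid for gid, _ in proteins]
    if len(set(ids)) != len(ids):
        dups = sorted({g for g in ids if ids.count(g) > 1})
        raise ValueError(f"duplicate gene ids: {', '.join(dups)}")
    edges: list[SimilarityEdge] = []
    for i in range(len(proteins)):
        gid_a, seq_a = proteins[i]
        for j in range(i + 1, len(proteins)):
            gid_b, seq_b = proteins[j]
            r = align_proteins(seq_a, seq_b, params)
            edges.append(
                SimilarityEdge(
                    protein_a=gid_a,
                    protein_b=gid_b,
                    evalue=r.evalue,
                    pct_identity=r.percent_identity,
                    passes=thresholds.passes(r.evalue, r.percent_identity),
                )
            )
    return edges


def cluster_phams(
    edges: Iterable[SimilarityEdge],
    all_proteins: Sequence[str],
) -> PhamPartition:
    """Single-linkage partition: connected components of passing edges.

    Pham ids are dense integers ordered by each component's
    lexicographically smallest member, so the output is independent of
    input ordering.
    """
    known = set(all_proteins)
    if len(known) != len(all_proteins):
        raise ValueError("duplicate protein ids")
    g = nx.Graph()
    g.add_nodes_from(all_proteins)
    for e in edges:
        if e.protein_a not in known or e.protein_b not in known:
            raise ValueError(
                f"edge references unknown protein: {e.protein_a}/{e.protein_b}"
            )
        if e.passes:
            g.add_edge(e.protein_a, e.protein_b)
    comps = sorted(nx.connected_components(g), key=lambda c: min(c))
    pham_of: dict[str, int] = {}
    members: dict[int, frozenset[str]] = {}
    for pid, comp in enumerate(comps, start=1):
        members[pid] = frozenset(comp)
        for gid in comp:
            pham_of[gid] = pid
    return PhamPartition(pham_of=pham_of, members=members)


def pham_summary(p: PhamPartition) -> PhamSummary:
    """Counts and one-decimal (half-up) percentages of the partition."""
    n_proteins = p.n_proteins
    n_phams = len(p.members)
    multi = [m for m in p.members.values() if len(m) >= 2]
    n_multi = len(multi)
    n_in_multi = sum(len(m) for m in multi)
    n_orphams = n_phams - n_multi
    return PhamSummary(
        n_proteins=n_proteins,
        n_phams=n_phams,
        n_multimember_phams=n_multi,
        n_proteins_in_multimember=n_in_multi,
        n_orphams=n_orphams,
        pct_multimember_phams=percent(n_multi, n_phams) if n_phams else 0.0,
        pct_proteins_in_multimember=(
            percent(n_in_multi, n_proteins) if n_proteins else 0.0
        ),
        pct_orphams=percent(n_orphams, n_proteins) if n_proteins else 0.0,
    )


def summary_from_counts(
    n_proteins: int, n_phams: int, n_multimember_phams: int,
    n_proteins_in_multimember: int,
) -> PhamSummary:
    """Summary arithmetic from already-tabulated counts.

    Builds a synthetic partition with the stated shape (multi-member phams
    of minimal size plus orphams) and summarizes it, so the percentage
    path is identical to the one used on real partitions.
    """
    n_orphams = n_proteins - n_proteins_in_multimember
    if n_phams != n_multimember_phams + n_orphams:
        raise ValueError("counts are not a consistent partition")
    pham_of: dict[str, int] = {}
    members: dict[int, frozenset[str]] = {}
    gene = 0
    # distribute the multi-member proteins over the multi-member phams
    base, extra = divmod(n_proteins_in_multimember - 2 * n_multimember_phams,
                         max(n_multimember_phams, 1))
    for k in range(n_multimember_phams):
        size = 2 + base + (1 if k < extra else 0)
        mem = []
        for _ in range(size):
            gid = f"g{gene:06d}"
            gene += 1
            pham_of[gid] = k + 1
            mem.append(gid)
        members[k + 1] = frozenset(mem)
    for k in range(n_orphams):
        gid = f"g{gene:06d}"
        gene += 1
        pid = n_multimember_phams + k + 1
        pham_of[gid] = pid
        members[pid] = frozenset([gid])
    return pham_summary(PhamPartition(pham_of=pham_of, members=members))


def _phage_of_map(genomes: Sequence[Genome]) -> dict[str, str]:
    out: dict[str, str] = {}
    for g in genomes:
        for gene in g.genes:
            out[gene.gene_id] = g.name
    return out


@dataclass(frozen=True)
class SharedPhamRow:
    phage: str
    n_shared_with_other_hosts: int
    n_focal_group_only: int
    n_orphams: int
    n_genes: int


def shared_pham_table(
    p: PhamPartition,
    genomes: Sequence[Genome],
    focal_group: set[str],
) -> list[SharedPhamRow]:
    """Classify each focal phage's genes by the reach of their pham.

    Categories (each gene exactly once): shared with a phage outside the
    focal group; shared only within the focal group (pham size >= 2, all
    members focal); orpham.
    """
    phage_of = _phage_of_map(genomes)
    names = {g.name for g in genomes}
    missing = focal_group - names
    if missing:
        raise ValueError(f"focal phages absent from genomes: {sorted(missing)}")
    rows = []
    for g in genomes:
        if g.name not in focal_group:
            continue
        outside = within = orph = 0
        for gene in g.genes:
            pid = p.pham_of[gene.gene_id]
            mem = p.members[pid]
            if len(mem) == 1:
                orph += 1
            elif any(phage_of[x] not in focal_group for x in mem):
                outside += 1
            else:
                within += 1
        rows.append(
            SharedPhamRow(
                phage=g.name,
                n_shared_with_other_hosts=outside,
                n_focal_group_only=within,
                n_orphams=orph,
                n_genes=len(g.genes),
            )
        )
    return rows


def remove_genome_recount(
    edges: Iterable[SimilarityEdge],
    genomes: Sequence[Genome],
    victim: str,
) -> tuple[PhamPartition, list[str]]:
    """Re-cluster without one genome; report surviving proteins that
    become orphams.

    Returns the new partition over the remaining proteins and the sorted
    list of gene ids that were in a multi-member pham before but are
    orphams after the victim's proteins are removed.
    """
    names = {g.name for g in genomes}
    if victim not in names:
        raise ValueError(f"unknown genome {victim!r}")
    victim_genes = {
        gene.gene_id for g in genomes if g.name == victim for gene in g.genes
    }
    all_ids = [
        gene.gene_id for g in genomes for gene in g.genes
    ]
    edges = list(edges)
    before = cluster_phams(edges, all_ids)
    kept_ids = [gid for gid in all_ids if gid not in victim_genes]
    kept_edges = [
        e
        for e in edges
        if e.protein_a not in victim_genes and e.protein_b not in victim_genes
    ]
    after = cluster_phams(kept_edges, kept_ids)
    newly_orphan = sorted(
        gid
        for gid in kept_ids
        if len(after.members[after.pham_of[gid]]) == 1
        and len(before.members[before.pham_of[gid]]) > 1
    )
    return after, newly_orphan


@dataclass(frozen=True)
class PhamCircle:
    pham_id: int
    entries: tuple[tuple[str, str], ...]  # (phage, gene_id) in circle order
    links: tuple[tuple[str, str], ...]  # unordered gene-id pairs


def pham_circle(
    p: PhamPartition,
    pham_id: int,
    genome_order: Sequence[str],
    phage_of: Mapping[str, str],
) -> PhamCircle:
    """Lay one pham's members on a circular genome order and link all pairs."""
    if pham_id not in p.members:
        raise ValueError(f"unknown pham {pham_id}")
    order = {name: k for k, name in enumerate(genome_order)}
    mem = sorted(
        p.members[pham_id], key=lambda gid: (order.get(phage_of[gid], len(order)), gid)
    )
    entries = tuple((phage_of[gid], gid) for gid in mem)
    links = tuple(
        (mem[i], mem[j]) for i in range(len(mem)) for j in range(i + 1, len(mem))
    )
    return PhamCircle(pham_id=pham_id, entries=entries, links=links)


def pham_domain_coverage(
    p: PhamPartition, domains: Mapping[str, Sequence[str]]
) -> float:
    """Percent of phams with at least one domain-annotated member (1 dp)."""
    if not p.members:
        return 0.0
    annotated = {gid for gid, hits in domains.items() if hits}
    n_hit = sum(1 for mem in p.members.values() if mem & annotated)
    return percent(n_hit, len(p.members))


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------


def edges_to_frame(edges: Sequence[SimilarityEdge]) -> "pandas.DataFrame":
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "protein_a": e.protein_a,
                "protein_b": e.protein_b,
                "evalue": e.evalue,
                "pct_identity": e.pct_identity,
                "passes": e.passes,
            }
            for e in edges
        ]
    )


def partition_to_frame(
    p: PhamPartition, phage_of: Mapping[str, str]
) -> "pandas.DataFrame":
    import pandas as pd

    rows = []
    for gid in sorted(p.pham_of):
        pid = p.pham_of[gid]
        size = len(p.members[pid])
        rows.append(
            {
                "gene_id": gid,
                "phage": phage_of.get(gid, ""),
                "pham_id": pid,
                "pham_size": size,
                "is_orpham": size == 1,
            }
        )
    return pd.DataFrame(rows)


def summary_to_json(s: PhamSummary) -> str:
    return json.dumps(s.__dict__, indent=2, sort_keys=True)


def genome_map_data(genome: Genome, p: PhamPartition) -> list[dict]:
    """Gene boxes for a linear genome map (colors keyed by pham id)."""
    boxes = []
    for gene in genome.genes:
        pid = p.pham_of[gene.gene_id]
        boxes.append(
            {
                "gene_id": gene.gene_id,
                "start": gene.start,
                "end": gene.end,
                "strand": gene.strand,
                "pham_id": pid,
                "pham_size": len(p.members[pid]),
                "color_index": 0 if len(p.members[pid]) == 1 else pid,
            }
        )
    return boxes
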