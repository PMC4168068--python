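"""Core-protein counting between genome pairs (CoreGenes-style).

A reference protein is a core gene with respect to a comparison genome
when its best local alignment raw score against any comparison protein
reaches the score threshold (default 75). The percentage matrix is
directional — each row is normalized by the reference genome's gene total
— and genomes whose mutual percentage reaches a cutoff (default 40%) in
either direction are grouped by connected components.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np

from ._util import percent
from .genome_io import Genome
from .similarity import ScoringParams, protein_raw_score


@dataclass(frozen=True)
class CoreScoreParams:
    score_threshold: float = 75.0

    def __post_init__(self):
        if self.score_threshold <= 0:
            raise ValueError("score_threshold must be positive")


@dataclass(frozen=True)
class CoreGenesMatrix:
    names: tuple[str, ...]
    counts: np.ndarray  # reference x comparison
    percentages: np.ndarray
    reference_gene_totals: tuple[int, ...]

    def as_frame(self) -> "pandas.DataFrame":
        """Table with 'count (pct%)' cells, rows labeled by gene totals."""
        import pandas as pd

        data = {}
        for c, name in enumerate(self.names):
            col = []
            for r in range(len(self.names)):
                col.append(f"{int(self.counts[r, c])} ({self.percentages[r, c]}%)")
            data[name] = col
        index = [
            f"{n} ({t} gp)" for n, t in zip(self.names, self.reference_gene_totals)
        ]
        return pd.DataFrame(data, index=index)


def core_gene_count(
    reference: Genome,
    comparison: Genome,
    score_params: CoreScoreParams | None = None,
    scoring: ScoringParams | None = None,
) -> int:
    """Number of reference proteins with a best hit >= the score floor."""
    score_params = score_params or CoreScoreParams()
    scoring = scoring or ScoringParams()
    if not reference.genes or not comparison.genes:
        raise ValueError("core_gene_count requires non-empty proteomes")
    count = 0
    comp = [g.aa_seq for g in comparison.genes]
    for gene in reference.genes:
        best = max(protein_raw_score(gene.aa_seq, c, scoring) for c in comp)
        if best >= score_params.score_threshold:
            count += 1
    return count


def percentage_from_counts(count: int, reference_total: int) -> float:
    """Two-decimal (half-up) core percentage for a planted count."""
    return percent(count, reference_total, ndigits=2)


def core_percentage_matrix(
    genomes: Sequence[Genome],
    score_params: CoreScoreParams | None = None,
    scoring: ScoringParams | None = None,
) -> CoreGenesMatrix:
    """Counts and percentages for every ordered (reference, comparison) pair."""
    if len(genomes) < 2:
        raise ValueError("need at least two genomes")
    n = len(genomes)
    counts = np.zeros((n, n), dtype=int)
    pcts = np.zeros((n, n), dtype=float)
    totals = tuple(len(g.genes) for g in genomes)
    for r in range(n):
        for c in range(n):
            if r == c:
                counts[r, c] = totals[r]
            else:
                counts[r, c] = core_gene_count(
                    genomes[r], genomes[c], score_params, scoring
                )
            pcts[r, c] = percentage_from_counts(int(counts[r, c]), totals[r])
    return CoreGenesMatrix(
        names=tuple(g.name for g in genomes),
        counts=counts,
        percentages=pcts,
        reference_gene_totals=totals,
    )


def group_by_core_threshold(
    m: CoreGenesMatrix, cutoff_pct: float = 40.0
) -> list[list[str]]:
    """Components of the graph with an edge when either directed
    percentage reaches the cutoff."""
    g = nx.Graph()
    g.add_nodes_from(m.names)
    n = len(m.names)
    for a in range(n):
        for b in range(a + 1, n):
            if m.percentages[a, b] >= cutoff_pct or m.percentages[b, a] >= cutoff_pct:
                g.add_edge(m.names[a], m.names[b])
    comps = sorted(nx.connected_components(g), key=lambda c: min(c))
    return [sorted(c) for c in comps]
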