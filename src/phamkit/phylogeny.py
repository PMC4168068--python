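"""Distance-based phylogeny of large terminase proteins and
pham-overlay inference of DNA packaging strategy.

The distance between two terminases is a p-distance, 1 minus the
fractional identity of their pairwise alignment; the tree is built with
the Saitou–Nei neighbor-joining algorithm with deterministic tie-breaking
and zero-clamped branch lengths. The tree is held in a scikit-bio
TreeNode, so Newick serialization and tip-to-tip distances come for free.

Packaging inference transfers an experimentally characterized strategy
(headful/circularly permuted, 3' cohesive ends, long direct terminal
repeats) to any phage whose large terminase shares a pham with a
characterized phage; a terminase that is an orpham, or whose pham has no
characterized member, stays undetermined. A pham containing conflicting
characterized strategies is an error — mixed-strategy phams would break
the premise of the transfer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from skbio import TreeNode

from .phams import PhamPartition
from .similarity import ScoringParams, align_proteins

HEADFUL = "headful_circularly_permuted"
COS_3PRIME = "cohesive_ends_3prime"
LONG_DTR = "long_direct_terminal_repeats"
UNDETERMINED = "undetermined"

STRATEGIES = (HEADFUL, COS_3PRIME, LONG_DTR, UNDETERMINED)


@dataclass(frozen=True)
class DistanceMatrix:
    taxa: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "d", d)
        if d.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(d), 0):
            raise ValueError("distance matrix diagonal must be zero")
        if (d < -1e-12).any():
            raise ValueError("distances must be non-negative")


@dataclass(frozen=True)
class PackagingCall:
    phage: str
    strategy: str
    evidence: str


class PackagingConflictError(ValueError):
    """A terminase pham contains phages with different known strategies."""


def terminase_distances(
    proteins: Sequence[tuple[str, str]], params: ScoringParams | None = None
) -> DistanceMatrix:
    """1 - fractional identity for every pair of terminase proteins."""
    if len(proteins) < 3:
        raise ValueError("need at least three taxa for a distance matrix")
    params = params or ScoringParams()
    names = tuple(name for name, _ in proteins)
    n = len(proteins)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r = align_proteins(proteins[i][1], proteins[j][1], params)
            d[i, j] = d[j, i] = 1.0 - r.percent_identity / 100.0
    return DistanceMatrix(taxa=names, d=d)


def neighbor_joining(m: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining with a trifurcating root.

    Ties on the Q criterion break toward the smallest (i, j) index pair
    in the current working order. A negative branch length is clamped to
    zero and the deficit moved to its sister so the pair's summed length
    is preserved.
    """
    n = len(m.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least three taxa")
    nodes: list[TreeNode] = [TreeNode(name=t) for t in m.taxa]
    d = m.d.astype(float).copy()

    def clamp_pair(li: float, lj: float, total: float) -> tuple[float, float]:
        if li < 0:
            li, lj = 0.0, total
        if lj < 0:
            li, lj = total, 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(nodes) > 3:
        r = len(nodes)
        sums = d.sum(axis=1)
        # Q[i, j] = (r - 2) d[i, j] - sums[i] - sums[j]
        q = (r - 2) * d - sums[:, None] - sums[None, :]
        np.fill_diagonal(q, np.inf)
        best = None
        for i in range(r):
            for j in range(i + 1, r):
                if best is None or q[i, j] < q[best[0], best[1]] - 1e-12:
                    best = (i, j)
        i, j = best
        li = 0.5 * d[i, j] + (sums[i] - sums[j]) / (2 * (r - 2))
        lj = d[i, j] - li
        li, lj = clamp_pair(li, lj, d[i, j])
        parent = TreeNode()
        nodes[i].length = li
        nodes[j].length = lj
        parent.extend([nodes[i], nodes[j]])
        # distances from the new node to everything remaining
        new_row = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(r) if k not in (i, j)]
        nd = np.zeros((r - 1, r - 1))
        nd[: r - 2, : r - 2] = d[np.ix_(keep, keep)]
        nd[-1, : r - 2] = nd[: r - 2, -1] = new_row[keep]
        d = nd
        nodes = [nodes[k] for k in keep] + [parent]

    # resolve the last three around a trifurcating root
    (a, b, c) = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    a.length = max(la, 0.0)
    b.length = max(lb, 0.0)
    c.length = max(lc, 0.0)
    root = TreeNode()
    root.extend([a, b, c])
    return root


def tree_to_newick(tree: TreeNode) -> str:
    """Newick string with branch lengths to six decimals."""
    clone = tree.copy()
    for node in clone.traverse():
        if node.length is not None:
            node.length = float(f"{node.length:.6f}")
    return str(clone).strip()


def infer_packaging(
    partition: PhamPartition,
    terminase_ids: Mapping[str, str],
    known: Mapping[str, str],
) -> list[PackagingCall]:
    """Assign packaging strategies by shared terminase pham membership."""
    for phage, strat in known.items():
        if strat not in STRATEGIES or strat == UNDETERMINED:
            raise ValueError(f"unknown strategy {strat!r} for {phage!r}")
    gene_to_phage = {gid: phage for phage, gid in terminase_ids.items()}
    calls: list[PackagingCall] = []
    for phage in sorted(terminase_ids):
        gid = terminase_ids[phage]
        pid = partition.pham_of.get(gid)
        if pid is None:
            raise ValueError(f"terminase {gid!r} missing from the partition")
        members = partition.members[pid]
        if len(members) == 1:
            calls.append(PackagingCall(phage, UNDETERMINED, "orpham"))
            continue
        mates = {
            gene_to_phage[g]
            for g in members
            if g in gene_to_phage and gene_to_phage[g] != phage
        }
        characterized = sorted(m for m in mates if m in known)
        strategies = {known[m] for m in characterized}
        if len(strategies) > 1:
            raise PackagingConflictError(
                f"pham {pid} mixes strategies {sorted(strategies)} "
                f"among {characterized}"
            )
        if not strategies:
            calls.append(PackagingCall(phage, UNDETERMINED, "no characterized phage in pham"))
        else:
            calls.append(
                PackagingCall(phage, strategies.pop(), characterized[0])
            )
    return calls


def packaging_to_frame(
    calls: Sequence[PackagingCall],
    partition: PhamPartition,
    terminase_ids: Mapping[str, str],
) -> "pandas.DataFrame":
    import pandas as pd

    rows = []
    for c in calls:
        gid = terminase_ids[c.phage]
        rows.append(
            {
                "phage": c.phage,
                "terminase_gene": gid,
                "pham_id": partition.pham_of[gid],
                "strategy": c.strategy,
                "evidence": c.evidence,
            }
        )
    return pd.DataFrame(rows)
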