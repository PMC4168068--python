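"""Synthetic phage cohort generator with known evolutionary ground truth.

An ancestral genome (random protein-coding genes with a realistic length
distribution, a designated tape-measure-protein gene, short intergenic
spacers, ~90% forward-strand genes, GC near 39%) is evolved down a random
bifurcating genealogy. Each branch can apply nucleotide substitutions
(codon-safe: start and stop codons are preserved and no internal stops
are created), gene loss, gene gain (novel composition-random genes that
become orphams by construction), and tandem duplication with extra
divergence; leaves can additionally receive a horizontal block of genes
from another leaf. Every emitted gene carries an ortholog-group label and
every event is logged, so pipeline output can be scored against truth.

All randomness flows through one numpy Generator seeded once per run:
identical parameters give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_io import FORWARD, REVERSE, Gene, Genome, translate_cds
from .similarity import reverse_complement

BASES = np.array(list("ACGT"))
STOPS = {"TAA", "TAG", "TGA"}
TMP_PRODUCT = "tape measure protein"


@dataclass(frozen=True)
class CohortParams:
    n_genomes: int = 6
    genome_length_target: int = 50_000
    genes_per_genome: int = 80
    forward_strand_fraction: float = 0.9
    gc_target: float = 0.39
    substitution_rate: float = 0.02
    gene_loss_prob: float = 0.02
    gene_gain_prob: float = 0.3
    duplication_prob: float = 0.1
    block_transfer_prob: float = 0.1
    tmp_length: int = 2400
    tmp_lengths: tuple[int, ...] | None = None
    seed: int = 0

    def __post_init__(self):
        for name in (
            "forward_strand_fraction",
            "gene_loss_prob",
            "gene_gain_prob",
            "duplication_prob",
            "block_transfer_prob",
        ):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_genomes < 1:
            raise ValueError("n_genomes must be >= 1")
        if self.genes_per_genome < 2:
            raise ValueError("genes_per_genome must be >= 2")
        if self.tmp_lengths is not None and len(self.tmp_lengths) != self.n_genomes:
            raise ValueError("tmp_lengths must list one length per genome")


@dataclass(frozen=True)
class SyntheticTruth:
    ortholog_group: dict[str, str]
    parent_group: dict[str, str]
    event_log: tuple[tuple[str, str, str], ...]  # (event, branch, detail)
    tree_newick: str


@dataclass
class _GeneState:
    group: str
    seq: str  # coding sequence incl. start and stop codons
    strand: str
    is_tmp: bool = False


@dataclass
class _GenomeState:
    genes: list[_GeneState]
    spacers: list[str]  # len(genes) + 1


class GenerationError(ValueError):
    pass


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(BASES, size=n, p=p))


def _random_codon(rng, gc: float) -> str:
    while True:
        c = _random_bases(rng, 3, gc)
        if c not in STOPS:
            return c


def _random_cds(rng, length_bp: int, gc: float) -> str:
    """A translatable CDS of the given length (multiple of 3, >= 9 bp)."""
    n_internal = length_bp // 3 - 2
    body = "".join(_random_codon(rng, gc) for _ in range(n_internal))
    return "ATG" + body + "TAA"


def _draw_gene_length(rng, median_bp: float) -> int:
    raw = rng.lognormal(mean=np.log(median_bp), sigma=0.5)
    bp = int(np.clip(raw, 150, 4500))
    return max(9, (bp // 3) * 3)


def _mutate_cds(rng, seq: str, rate: float) -> str:
    """Per-site substitutions that keep the CDS translatable."""
    if rate <= 0:
        return seq
    chars = list(seq)
    n = len(chars)
    hits = np.nonzero(rng.random(n - 6) < rate)[0] + 3  # spare start/stop
    for pos in hits:
        old = chars[pos]
        alts = [b for b in "ACGT" if b != old]
        new = alts[rng.integers(3)]
        codon_start = (pos // 3) * 3
        trial = chars[codon_start:pos] + [new] + chars[pos + 1 : codon_start + 3]
        if "".join(trial) in STOPS:
            continue  # skip rather than create a premature stop
        chars[pos] = new
    return "".join(chars)


def _mutate_plain(rng, seq: str, rate: float) -> str:
    if rate <= 0 or not seq:
        return seq
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for pos in hits:
        alts = [b for b in "ACGT" if b != chars[pos]]
        chars[pos] = alts[rng.integers(3)]
    return "".join(chars)


def _random_topology(rng, leaves: list[int]):
    """Random bifurcating tree as nested tuples of leaf indices."""
    if len(leaves) == 1:
        return leaves[0]
    k = int(rng.integers(1, len(leaves)))
    return (_random_topology(rng, leaves[:k]), _random_topology(rng, leaves[k:]))


def _topology_newick(node) -> str:
    if isinstance(node, int):
        return f"L{node}"
    return "(" + ",".join(_topology_newick(c) for c in node) + ")"


def mutate_fixed_positions(seq: str, k: int, seed: int) -> str:
    """Copy of ``seq`` differing at exactly ``k`` distinct positions."""
    if k > len(seq):
        raise ValueError(f"k={k} exceeds sequence length {len(seq)}")
    rng = np.random.default_rng(seed)
    chars = list(seq.upper())
    positions = rng.choice(len(chars), size=k, replace=False)
    for pos in positions:
        alts = [b for b in "ACGT" if b != chars[pos]]
        chars[pos] = alts[rng.integers(3)]
    return "".join(chars)


def generate_cohort(cp: CohortParams) -> tuple[list[Genome], SyntheticTruth]:
    rng = np.random.default_rng(cp.seed)
    gc = cp.gc_target
    median_bp = max(
        150.0, 0.92 * cp.genome_length_target / cp.genes_per_genome
    )

    # ancestral genome
    genes: list[_GeneState] = []
    tmp_slot = int(rng.integers(cp.genes_per_genome))
    for k in range(cp.genes_per_genome):
        if k == tmp_slot:
            bp = max(9, (cp.tmp_length // 3) * 3)
        else:
            bp = _draw_gene_length(rng, median_bp)
        strand = FORWARD if rng.random() < cp.forward_strand_fraction else REVERSE
        genes.append(
            _GeneState(
                group=f"og{k:03d}",
                seq=_random_cds(rng, bp, gc),
                strand=strand,
                is_tmp=(k == tmp_slot),
            )
        )
    spacers = [
        _random_bases(rng, int(rng.integers(2, 151)), gc)
        for _ in range(cp.genes_per_genome + 1)
    ]
    root = _GenomeState(genes=genes, spacers=spacers)

    events: list[tuple[str, str, str]] = []
    counters = {"novel": 0, "dup": 0}

    def branch_evolve(state: _GenomeState, branch: str) -> _GenomeState:
        new_genes = [
            _GeneState(g.group, _mutate_cds(rng, g.seq, cp.substitution_rate),
                       g.strand, g.is_tmp)
            for g in state.genes
        ]
        new_spacers = [
            _mutate_plain(rng, s, cp.substitution_rate) for s in state.spacers
        ]
        st = _GenomeState(new_genes, new_spacers)
        # loss (the tape measure gene is protected; cohorts need one per genome)
        keep_mask = rng.random(len(st.genes)) >= cp.gene_loss_prob
        lost = [
            g for g, keep in zip(st.genes, keep_mask) if not keep and not g.is_tmp
        ]
        if lost and len(st.genes) - len(lost) >= 2:
            for g in lost:
                idx = st.genes.index(g)
                st.genes.pop(idx)
                st.spacers.pop(idx + 1)
                events.append(("loss", branch, g.group))
        # gain of a novel gene
        if rng.random() < cp.gene_gain_prob:
            counters["novel"] += 1
            group = f"novel{counters['novel']:03d}"
            bp = _draw_gene_length(rng, median_bp)
            pos = int(rng.integers(len(st.genes) + 1))
            st.genes.insert(
                pos, _GeneState(group, _random_cds(rng, bp, gc), FORWARD)
            )
            st.spacers.insert(pos + 1, _random_bases(rng, int(rng.integers(2, 151)), gc))
            events.append(("gain", branch, group))
        # tandem duplication with extra divergence
        if rng.random() < cp.duplication_prob and st.genes:
            idx = int(rng.integers(len(st.genes)))
            src = st.genes[idx]
            counters["dup"] += 1
            group = f"{src.group}.dup{counters['dup']}"
            dup_seq = _mutate_cds(rng, src.seq, 3 * cp.substitution_rate)
            st.genes.insert(idx + 1, _GeneState(group, dup_seq, src.strand))
            st.spacers.insert(
                idx + 2, _random_bases(rng, int(rng.integers(2, 151)), gc)
            )
            truth_parent[group] = src.group
            events.append(("duplication", branch, f"{src.group}->{group}"))
        return st

    truth_parent: dict[str, str] = {}
    topo = _random_topology(rng, list(range(cp.n_genomes)))
    leaf_states: dict[int, _GenomeState] = {}

    def walk(node, state: _GenomeState, path: str):
        if isinstance(node, int):
            leaf_states[node] = state
            return
        for ci, child in enumerate(node):
            child_path = f"{path}.{ci}"
            walk(child, branch_evolve(state, child_path), child_path)

    if cp.n_genomes == 1:
        leaf_states[0] = branch_evolve(root, "root.0")
    else:
        walk(topo, root, "root")

    # horizontal block transfer between leaves
    if cp.n_genomes >= 2:
        for leaf in range(cp.n_genomes):
            if rng.random() >= cp.block_transfer_prob:
                continue
            donor = int(rng.choice([k for k in range(cp.n_genomes) if k != leaf]))
            src = leaf_states[donor]
            if len(src.genes) < 2:
                continue
            width = int(rng.integers(2, min(4, len(src.genes)) + 1))
            start = int(rng.integers(len(src.genes) - width + 1))
            block = [
                _GeneState(g.group, g.seq, g.strand)
                for g in src.genes[start : start + width]
            ]
            dst = leaf_states[leaf]
            pos = int(rng.integers(len(dst.genes) + 1))
            for off, g in enumerate(block):
                dst.genes.insert(pos + off, g)
                dst.spacers.insert(
                    pos + off + 1, _random_bases(rng, int(rng.integers(2, 151)), gc)
                )
            events.append(
                (
                    "block_transfer",
                    f"L{donor}->L{leaf}",
                    ",".join(g.group for g in block),
                )
            )

    # optional per-genome tape-measure gene resizing
    if cp.tmp_lengths is not None:
        for leaf in range(cp.n_genomes):
            target = max(9, (cp.tmp_lengths[leaf] // 3) * 3)
            st = leaf_states[leaf]
            for g in st.genes:
                if g.is_tmp:
                    g.seq = _resize_cds(rng, g.seq, target)
                    events.append(("tmp_resize", f"L{leaf}", str(target)))

    genomes: list[Genome] = []
    ortholog: dict[str, str] = {}
    for leaf in range(cp.n_genomes):
        name = f"SimPhage{leaf + 1:02d}"
        st = leaf_states[leaf]
        parts: list[str] = [st.spacers[0]]
        cursor = len(st.spacers[0])
        gene_records: list[Gene] = []
        for k, g in enumerate(st.genes):
            on_genome = g.seq if g.strand == FORWARD else reverse_complement(g.seq)
            start, end = cursor, cursor + len(g.seq)
            gid = f"{name}_gp{k + 1}"
            gene_records.append(
                Gene(
                    gene_id=gid,
                    phage=name,
                    start=start,
                    end=end,
                    strand=g.strand,
                    nt_seq=g.seq,
                    aa_seq=translate_cds(g.seq),
                    product=TMP_PRODUCT if g.is_tmp else None,
                )
            )
            ortholog[gid] = g.group
            parts.append(on_genome)
            cursor = end
            parts.append(st.spacers[k + 1])
            cursor += len(st.spacers[k + 1])
        genomes.append(
            Genome(
                name=name,
                sequence="".join(parts),
                genes=tuple(gene_records),
                host="Paenibacillus larvae (synthetic)",
                accession=f"SIM{cp.seed:06d}.{leaf + 1}",
            )
        )

    truth = SyntheticTruth(
        ortholog_group=ortholog,
        parent_group=dict(truth_parent),
        event_log=tuple(events),
        tree_newick=_topology_newick(topo) + ";",
    )
    return genomes, truth


def _resize_cds(rng, seq: str, target_bp: int) -> str:
    """Trim or extend a CDS to a target length by editing internal codons."""
    body = seq[3:-3]
    want = target_bp - 6
    while len(body) > want:
        cut = int(rng.integers(len(body) // 3)) * 3
        body = body[:cut] + body[cut + 3 :]
    while len(body) < want:
        at = int(rng.integers(len(body) // 3 + 1)) * 3
        src = int(rng.integers(max(len(body) // 3, 1))) * 3
        codon = body[src : src + 3] if body else "GCT"
        if not codon or codon in STOPS:
            codon = "GCT"
        body = body[:at] + codon + body[at:]
    return seq[:3] + body + seq[-3:]


def tmp_gene(genome: Genome) -> Gene:
    """The designated tape-measure-protein gene of a synthetic genome."""
    for g in genome.genes:
        if g.product == TMP_PRODUCT:
            return g
    raise ValueError(f"{genome.name}: no tape measure protein gene annotated")


def make_coisolation_mixture(
    g1: Genome,
    g2: Genome,
    coverage: float = 5.0,
    fragment_length: int = 500,
    weight1: float = 1.0,
    weight2: float = 1.0,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], dict[str, str]]:
    """Interleaved read-like fragments from two co-isolated genomes.

    Returns FASTA-ready (fragment_id, sequence) records and a truth map
    fragment_id -> source genome name. Fragment counts follow the
    requested per-genome coverage (coverage * weight), rounded.
    """
    if g1.name == g2.name:
        raise ValueError("co-isolation mixture needs two distinct genomes")
    rng = np.random.default_rng(seed)
    records: list[tuple[str, str]] = []
    truth: dict[str, str] = {}
    for genome, weight in ((g1, weight1), (g2, weight2)):
        L = len(genome.sequence)
        flen = min(fragment_length, L)
        n_frags = int(round(coverage * weight * L / flen))
        for k in range(n_frags):
            start = int(rng.integers(0, L - flen + 1))
            fid = f"{genome.name}_frag{k + 1:05d}"
            records.append((fid, genome.sequence[start : start + flen]))
            truth[fid] = genome.name
    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    return records, truth
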