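import random

import pytest

from phamkit.genome_io import FORWARD, REVERSE, Gene, Genome, translate_cds
from phamkit.synthetic import CohortParams, generate_cohort

AA = "ACDEFGHIKLMNPQRSTVWY"
NT = "ACGT"


def random_peptide(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(AA) for _ in range(length))


def random_dna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(NT) for _ in range(length))


def mutate_peptide(rng: random.Random, seq: str, frac: float) -> str:
    out = list(seq)
    for pos in rng.sample(range(len(seq)), int(frac * len(seq))):
        out[pos] = rng.choice([c for c in AA if c != out[pos]])
    return "".join(out)


_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}


def cds_for_peptide(aa_seq: str) -> str:
    """Reverse-translate a peptide into a CDS (one fixed codon per residue)."""
    return "ATG" + "".join(_CODON[c] for c in aa_seq) + "TAA"


def make_genome(name: str, gene_specs, host=None) -> Genome:
    """Build a Genome from (aa-free) CDS nucleotide specs laid end to end.

    gene_specs: list of (cds_nt, strand); spacers of 10 N-free bases are
    inserted between genes.
    """
    rng = random.Random(hash(name) & 0xFFFF)
    parts = []
    genes = []
    cursor = 0
    for k, (cds, strand) in enumerate(gene_specs, start=1):
        spacer = random_dna(rng, 10)
        parts.append(spacer)
        cursor += len(spacer)
        start, end = cursor, cursor + len(cds)
        on_genome = cds if strand == FORWARD else _revcomp(cds)
        parts.append(on_genome)
        cursor = end
        genes.append(
            Gene(
                gene_id=f"{name}_gp{k}",
                phage=name,
                start=start,
                end=end,
                strand=strand,
                nt_seq=cds,
                aa_seq=translate_cds(cds),
            )
        )
    return Genome(name=name, sequence="".join(parts), genes=tuple(genes), host=host)


def _revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return "".join(comp[c] for c in reversed(seq))


@pytest.fixture(scope="session")
def small_cohort():
    """A 4-genome, ~10-gene cohort with gains but no duplications or
    transfers, divergent enough to exercise clustering but cheap."""
    cp = CohortParams(
        n_genomes=4,
        genes_per_genome=10,
        genome_length_target=6000,
        substitution_rate=0.02,
        gene_gain_prob=0.5,
        duplication_prob=0.0,
        block_transfer_prob=0.0,
        seed=7,
    )
    return generate_cohort(cp)
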