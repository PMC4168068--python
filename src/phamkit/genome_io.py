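"""Genome and protein I/O plus per-genome descriptive statistics.

Internal coordinates are 0-based half-open throughout; GenBank's 1-based
inclusive convention is converted at the file boundary. Genomes are linear:
a CDS wrapping the origin is rejected. Translation uses NCBI genetic code
table 11 (bacterial) unless configured otherwise.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from ._util import mean_sd, round_half_up

FORWARD = "forward"
REVERSE = "reverse"

DEFAULT_GENETIC_CODE = 11


class GenomeIOError(ValueError):
    """Malformed genome data (parse failures, invalid CDS records)."""


@dataclass(frozen=True)
class Gene:
    """A protein-coding gene on a phage genome.

    ``start``/``end`` are 0-based half-open on the forward strand of the
    genome; ``nt_seq`` is the coding-strand sequence (reverse-complemented
    for reverse-strand genes); ``aa_seq`` excludes the terminal stop.
    """

    gene_id: str
    phage: str
    start: int
    end: int
    strand: str
    nt_seq: str
    aa_seq: str
    product: str | None = None

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise GenomeIOError(
                f"{self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in (FORWARD, REVERSE):
            raise GenomeIOError(f"{self.gene_id}: bad strand {self.strand!r}")
        if not self.aa_seq:
            raise GenomeIOError(f"{self.gene_id}: empty protein sequence")


@dataclass(frozen=True)
class Genome:
    """A named, annotated phage genome with genes ordered by start."""

    name: str
    sequence: str
    genes: tuple[Gene, ...] = ()
    host: str | None = None
    accession: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "genes", tuple(self.genes))
        last = -1
        for g in self.genes:
            if g.end > len(self.sequence):
                raise GenomeIOError(
                    f"{g.gene_id}: end {g.end} beyond genome length "
                    f"{len(self.sequence)}"
                )
            if g.start < last:
                raise GenomeIOError(f"{self.name}: genes not sorted by start")
            last = g.start

    @property
    def gc_fraction(self) -> float:
        s = self.sequence.upper()
        if not s:
            return 0.0
        return (s.count("G") + s.count("C")) / len(s)

    def proteins(self) -> list[tuple[str, str]]:
        """(gene_id, aa_seq) pairs in genome order."""
        return [(g.gene_id, g.aa_seq) for g in self.genes]


@dataclass(frozen=True)
class GenomeStats:
    length_bp: int
    n_genes: int
    n_forward: int
    n_reverse: int
    gc_percent: float


def translate_cds(nt_seq: str, table: int = DEFAULT_GENETIC_CODE) -> str:
    """Translate a coding sequence, dropping the terminal stop if present."""
    if len(nt_seq) % 3 != 0:
        raise GenomeIOError(f"CDS length {len(nt_seq)} not a multiple of 3")
    aa = str(Seq(nt_seq).translate(table=table))
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        raise GenomeIOError("internal stop codon in CDS translation")
    if not aa:
        raise GenomeIOError("CDS translates to an empty protein")
    return aa


def read_genbank(
    path: str | Path,
    genetic_code: int = DEFAULT_GENETIC_CODE,
    trust_translation: bool = True,
) -> Genome:
    """Read a single-record GenBank flat file into a :class:`Genome`.

    Every CDS feature becomes a :class:`Gene`. The ``/translation``
    qualifier is used verbatim when present (checked against the spliced
    nucleotide sequence unless a ``transl_except``-style discrepancy is
    tolerated via ``trust_translation=False`` is *not* offered: a mismatch
    is a hard error); otherwise the CDS is translated with the configured
    genetic code.
    """
    path = Path(path)
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except ValueError as exc:
        raise GenomeIOError(f"{path}: malformed GenBank record: {exc}") from exc
    if len(records) != 1:
        raise GenomeIOError(
            f"{path}: expected exactly one LOCUS record, found {len(records)}"
        )
    rec = records[0]
    sequence = str(rec.seq).upper()
    name = rec.annotations.get("source_name") or rec.name or rec.id
    host = None
    for feat in rec.features:
        if feat.type == "source":
            host = feat.qualifiers.get("host", [None])[0]
    accession = rec.id if rec.id and rec.id != "<unknown id>" else None
    if accession == name:  # no real accession was recorded at write time
        accession = None

    genes: list[Gene] = []
    n = 0
    for feat in rec.features:
        if feat.type != "CDS":
            continue
        n += 1
        loc = feat.location
        if loc is None:
            raise GenomeIOError(f"{path}: CDS #{n} has no location")
        start, end = int(loc.start), int(loc.end)
        if len(loc.parts) > 1 and int(loc.parts[0].start) > int(loc.parts[-1].start):
            raise GenomeIOError(
                f"{path}: CDS #{n} spans the genome origin; circular "
                "genomes are not supported"
            )
        strand = REVERSE if loc.strand == -1 else FORWARD
        nt = str(feat.extract(rec.seq)).upper()
        table = int(feat.qualifiers.get("transl_table", [genetic_code])[0])
        translation = feat.qualifiers.get("translation", [None])[0]
        if translation is None:
            try:
                translation = translate_cds(nt, table)
            except GenomeIOError as exc:
                raise GenomeIOError(
                    f"{path}: CDS #{n} at {start}..{end} lacks /translation "
                    f"and is not translatable: {exc}"
                ) from exc
        else:
            translation = str(translation)
            if trust_translation:
                check = translate_cds(nt, table)
                if check != translation:
                    raise GenomeIOError(
                        f"{path}: CDS #{n} /translation disagrees with the "
                        "spliced nucleotide sequence"
                    )
        gid = feat.qualifiers.get("locus_tag", [f"{name}_gp{n}"])[0]
        product = feat.qualifiers.get("product", [None])[0]
        genes.append(
            Gene(
                gene_id=gid,
                phage=name,
                start=start,
                end=end,
                strand=strand,
                nt_seq=nt,
                aa_seq=translation,
                product=product,
            )
        )
    genes.sort(key=lambda g: (g.start, g.end, g.gene_id))
    return Genome(
        name=name, sequence=sequence, genes=tuple(genes), host=host, accession=accession
    )


def write_genbank(genome: Genome, path: str | Path) -> None:
    """Write a Genome as a single-record GenBank flat file."""
    rec = SeqRecord(
        Seq(genome.sequence),
        id=genome.accession or genome.name,
        name=genome.name[:16],
        description=f"{genome.name} phage genome",
        annotations={"molecule_type": "DNA", "source_name": genome.name},
    )
    src = SeqFeature(
        FeatureLocation(0, len(genome.sequence), strand=1), type="source"
    )
    if genome.host:
        src.qualifiers["host"] = [genome.host]
    rec.features.append(src)
    for g in genome.genes:
        feat = SeqFeature(
            FeatureLocation(g.start, g.end, strand=1 if g.strand == FORWARD else -1),
            type="CDS",
        )
        feat.qualifiers["locus_tag"] = [g.gene_id]
        feat.qualifiers["transl_table"] = [str(DEFAULT_GENETIC_CODE)]
        feat.qualifiers["translation"] = [g.aa_seq]
        if g.product:
            feat.qualifiers["product"] = [g.product]
        rec.features.append(feat)
    with open(path, "w") as fh:
        SeqIO.write([rec], fh, "genbank")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA into (id, sequence) pairs; duplicate IDs are an error."""
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise GenomeIOError(f"{path}: empty or unreadable FASTA file")
    seen: dict[str, int] = {}
    for rid, _ in records:
        seen[rid] = seen.get(rid, 0) + 1
    dups = sorted(r for r, k in seen.items() if k > 1)
    if dups:
        raise GenomeIOError(f"{path}: duplicate FASTA ids: {', '.join(dups)}")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (id, sequence) pairs as 60-column-wrapped FASTA."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def genome_stats(genome: Genome) -> GenomeStats:
    """Length, gene counts by strand, and GC% (two decimals, half-up)."""
    n_fwd = sum(1 for g in genome.genes if g.strand == FORWARD)
    n_rev = len(genome.genes) - n_fwd
    return GenomeStats(
        length_bp=len(genome.sequence),
        n_genes=len(genome.genes),
        n_forward=n_fwd,
        n_reverse=n_rev,
        gc_percent=round_half_up(100 * genome.gc_fraction, 2),
    )


def cohort_gc_summary(genomes: Sequence[Genome]) -> tuple[float, float]:
    """Mean and sample sd of per-genome GC%, both to two decimals."""
    if len(genomes) < 2:
        raise ValueError("cohort_gc_summary needs at least two genomes")
    return mean_sd([genome_stats(g).gc_percent for g in genomes], ndigits=2)


def stats_table(genomes: Sequence[Genome]) -> "pandas.DataFrame":
    """Per-genome stats as a DataFrame matching the TSV export schema."""
    import pandas as pd

    rows = []
    for g in genomes:
        s = genome_stats(g)
        rows.append(
            {
                "phage": g.name,
                "accession": g.accession or "",
                "length_bp": s.length_bp,
                "n_genes": s.n_genes,
                "n_forward": s.n_forward,
                "n_reverse": s.n_reverse,
                "gc_percent": s.gc_percent,
            }
        )
    return pd.DataFrame(rows)
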