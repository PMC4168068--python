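# Methods notes

## Protein comparison and the dual pham cutoff

Protein pairs are scored with exact Smith–Waterman under BLOSUM62 and
affine gap penalties 11 (open) / 1 (extend) — the classic protein-BLAST
parameterization — via Biopython's PairwiseAligner (exact dynamic
programming, not heuristic seeding). The raw score *S* is converted to an
E-value with the Karlin–Altschul formula `E = K·m·n·exp(−λS)` using the
published gapped BLOSUM62-11/1 constants λ = 0.267, K = 0.041. The search
space defaults to m·n per pair, because the pipeline compares proteins
pairwise rather than against a fixed database; a `fixed_db` policy exists
for users replaying database-style E-values. Ambiguous residues (X) score
0 against everything.

Percent identity — the second half of the pham cutoff — is measured on a
*global* alignment of the two full-length proteins under the same matrix
and gap costs, with end gaps penalized. This matters: the best local
alignment of two *unrelated* proteins is a short island whose identity
routinely exceeds 32.5%, so a local-identity cutoff would link nearly
every pair and abolish orphams. Full-length identity is the quantity a
ClustalO-style comparison reports, drops to ~5–15% for unrelated
proteins, and preserves the intended meaning of the 32.5% threshold. Both
metrics are computed on the canonically ordered pair, so every result is
exactly symmetric in its arguments.

An edge passes when `E < 1e-50` **or** `identity > 32.5%`; both
inequalities are strict, so boundary values fail. Phams are connected
components of the passing graph (single linkage), pham ids are dense
integers assigned by each component's lexicographically smallest gene id
(stable under any input permutation), and identical duplicate sequences
in one genome remain distinct nodes so within-genome duplicates can share
a pham.

Reported percentages use exact integer-ratio Decimal arithmetic and
round-half-up (one decimal for pham fractions, two for core-gene
percentages and GC), matching the formatting conventions of the report
tables this pipeline emulates.

## Nucleotide identity and dotplots

Whole-genome identity is the fraction of identical columns in an optimal
global alignment with match +1, mismatch −1, gap −2 (linear). The DP is
vectorized over anti-diagonals with a deterministic tie-break (diagonal,
then gap-in-second-sequence, then gap-in-first). Problems up to 4 × 10⁷
cells run the full matrix; larger ones use an adaptive band around the
main diagonal whose width doubles until the score is stable between
consecutive widths. For the near-identical genome pairs this operation is
used on (e.g. two ~54 kb genomes differing at 80 sites), the optimum is
near-diagonal and the banded result is exact; a long *and* deeply
divergent pair would exceed the band cap and raises rather than returning
a silently sub-optimal score. Dotplots are exact word matches with
reverse-complement words indexed separately for nucleotide input.

## Core genes

A reference protein counts as core with respect to a comparison genome
when its best local raw score against any comparison protein is ≥ 75 —
the conventional default score floor, interpreted as a raw-score floor on
the unidirectional best hit (no reciprocal-best filtering, mirroring
default usage of CoreGenes-style tools). Whether that floor should be raw
or bit score is genuinely underdetermined; raw score was chosen and the
threshold is an exposed parameter. The percentage matrix is directional
(row = reference, normalized by the reference gene total), and the 40%
grouping rule links two genomes when *either* direction reaches the
cutoff, then takes connected components.

## Neighbor joining and packaging inference

Terminase distances are p-distances, 1 − fractional identity of the
pairwise alignment — deliberately not a substitution-model distance,
because the tree's role here is pham-consistency checking and display,
not branch-length inference. The NJ implementation is the standard
Saitou–Nei agglomeration with two determinism guarantees: ties on the Q
criterion break toward the smallest index pair, and a negative branch
length is clamped to zero with the deficit moved to its sister so the
joined pair's summed length is preserved. The result is an unrooted tree
with a trifurcating root, held in a scikit-bio TreeNode and serialized as
Newick with six-decimal branch lengths. On additive matrices the
algorithm reproduces the generating tree's path lengths exactly (tested
on random trees up to 8 leaves).

Packaging inference transfers a characterized strategy to any phage whose
large terminase shares a pham with a characterized phage. A pham
containing two *different* characterized strategies raises an error
rather than guessing — mixed-strategy phams would invalidate the
transfer's premise. Orpham terminases, and phams with no characterized
member, stay `undetermined`; a determinate call always names its evidence
phage.

## Morphology

Feature summaries are mean ± sample (n−1) standard deviation, one
decimal. Cross-phage aggregates may include duplicate-valued phages when
a phage was published only as "indistinguishable from" another — the
caller controls this by listing the duplicate's values explicitly.
Morphotype rules: contractile sheath ⇒ myovirus; otherwise capsid
height/width above the elongation cutoff (default 1.2) ⇒ elongated
siphovirus, else round; missing measurements ⇒ unclassified. The 1.2
default sits between the observed elongated (≥ ~1.47) and round (≤ ~1.11)
aspect ratios and is configurable. Co-isolation matching is rank order:
longest TMP gene ↔ longest tail. Ties make the assignment ambiguous and
raise; ratios between consecutive ranked pairs are reported to two
decimals.

## Synthetic cohorts: what they emulate and what they do not

The generator's defaults describe a realistic small-myovirus cohort:
~50 kb genomes, 80 genes, 90% forward strand, GC target 0.39, gene
lengths log-normal (median ≈ 0.92 × genome length / gene count, clipped
to 150–4,500 bp) so tape-measure-scale genes occur, intergenic spacers of
2–150 bp, no overlapping genes. Substitutions are uniform at the
nucleotide level (2% per site per branch by default), synonymous and
non-synonymous alike, with start/stop codons preserved and premature
stops rejected; protein divergence is therefore measured, not targeted.
Gains insert composition-random genes that become orphams by construction
when gained on a terminal branch; duplications are tandem with 3× extra
divergence and carry a parent-group back-reference; block transfers copy
2–4 contiguous genes between leaves. One numpy Generator seeded once per
run makes output byte-identical for identical parameters. The observed GC
of emitted genomes runs ~1–1.7 points above target because stop-codon
rejection removes AT-rich codons; this stays within the ±2-point
tolerance the tests assert.

What passing tests on these cohorts show: the clustering, counting, and
matrix machinery recovers planted ortholog structure when within-group
identity is comfortably above the 32.5% cutoff and between-group identity
comfortably below it. What they do not show: behavior on real mosaic
phage genomes with codon bias, recombination hotspots, overlapping genes,
or borderline-identity families — there the pham membership of borderline
pairs can differ from heuristic-BLAST pipelines, since this package uses
exact alignment.

## Problem sizes and numerical choices

Tests run cohorts of 2–4 genomes with 5–12 genes each, which exercises
every code path (the all-vs-all stage is quadratic in total protein
count); the genome-scale identity check uses a full 54,312-nt pair.
Degenerate inputs are errors, not silent results: empty sequences,
empty proteomes, duplicate FASTA/gene ids, circular-spanning CDS
features, /translation qualifiers that disagree with the spliced
sequence, asymmetric distance matrices, tied lengths in co-isolation
matching. GenBank output is single-record, linear, translation table 11
by default. Pipeline outputs are write-once and the manifest omits only
the output directory, so a manifest plus a fresh directory reproduces a
run byte for byte.

## Known limitations

- No heuristic seeding: all-vs-all alignment is exact and quadratic, fine
  for cohorts of tens of genomes, not for hundred-genome databases.
- ANI is whole-genome global-alignment identity, not fragment-based ANI;
  long highly divergent pairs are rejected by the band cap.
- Packaging inference is only as good as the supplied characterized set.
- The simulator does not model codon usage, sequencing error, or
  assembly artifacts.
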