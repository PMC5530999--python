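# Methods

This note records the models, algorithms and numerical choices behind
`baitkit`, what the synthetic data does and does not emulate, and the
known limitations.

## Alignment engine

All similarity decisions reduce to two exact dynamic programmes over the
scoring scheme match = +1, mismatch = −1, gap of length L = −(2 + L)
(affine: open 2, extend 1):

* **Local** (Smith–Waterman) with an optional diagonal band. Ties between
  equal-scoring end cells resolve to the smallest query end coordinate,
  then subject end; within a cell the preference is diagonal, then gap in
  query, then gap in subject. The traceback also reports the gapless runs
  of the alignment (`(q_start, q_end, diagonal)`), which the spliced
  mapper consumes.
* **Global** (Needleman–Wunsch) with penalised end gaps, used for percent
  identity between full-length candidate homologues. Identity is
  matches / alignment columns, gaps included (the convention of BLAST
  output). Because tied optimal alignments can differ slightly in column
  count, the two sequences are ordered canonically before aligning so
  identity is exactly symmetric.

Ns and IUPAC ambiguity codes never match anything, including themselves.
This is deliberately conservative: an ambiguous base contributes no
evidence of identity.

The production search (`find_homologues`) is seeded: exact 11-mers are
collected per subject strand, supplemented by paired 7-mers (two short
seeds on one diagonal within 50 bp — long-word seeding alone can miss a
100 bp homologue at 75% identity, whose chance of containing a preserved
11-mer is only ~98%). Seeds are clustered by diagonal; clusters whose
diagonal moves by more than the band (15 bp) split, so spliced exons
yield separate hits. Sparsely seeded clusters are verified cheaply before
the DP: a 60 bp window on the cluster's dominant diagonal must match at
>= 62% (random sequence matches at 25%, true homologues at >= 70%, so the
gate is wide on both sides). Surviving clusters are aligned with the
exact banded DP in a window padded by 400 bp; the result is therefore the
true local optimum whenever the optimum lies in the window, which is what
makes seeded-vs-exact hit agreement achievable at the 75%/100 bp
operating point.

Alignment *score* — not only identity and length — separates homology
from chance: the maximal chance local alignment between unrelated
kilobase sequences reaches scores around 25–35 (and identities near 60%
over 100+ columns), while genuine homologues above the clustering floor
share hundreds of score units. Cluster edges therefore require score
>= 100 (`cluster_min_score`) in both directions. E-values are not
computed; the score floor plays their role at desk scale.

## Discovery

Homologue clusters are connected components of reciprocal hits between
different transcriptomes at a permissive identity floor
(`cluster_min_identity` = 0.55), so that divergent homologue groups are
*formed* and then *rejected* by the explicit >= 75% filter rather than
silently never found. The cluster representative is its longest member
(ties by lexicographic id).

Copy number:

* **Intra-source duplicates.** Two same-source members below 99% identity
  mark the cluster multi-copy (paralog chaining would otherwise pass
  silently); above 99% they are treated as assembly/isoform redundancy.
* **Genome route.** The representative is mapped to the genome; hits on
  one scaffold and strand closer than `locus_merge_gap` (10 kb) chain
  into one locus. Loci with chained identity >= 0.75 and query coverage
  >= 0.5 count; one locus = single, two or more = multi. Tandem
  duplicates closer than 10 kb would merge into one locus — a documented
  blind spot of the gap rule.
* **Catalogue route** (no genome). Single iff the best catalogue match at
  >= 0.70 identity is flagged single/mostly-single and the second-best
  entry scores < 0.9 x the best. Flags are read from the catalogue FASTA
  descriptions (`single`, `mostly_single`, `multi`; an unflagged entry in
  a single-copy catalogue counts as single).

Gene models are built from the maximal colinear chain of hits (selected
by total matched bases, ties to the leftmost genomic start), exploded
into their gapless runs. Runs shorter than 20 bp are discarded as
alignment noise when longer runs exist — local optima occasionally tack a
short gapped "sneak extension" across an exon boundary onto a hit — and
remaining diagonal inversions drop the shorter offender. Exon boundaries
are then refined so the exon set exactly tiles the transcript: each
transcript stretch between consecutive runs is assigned to the two
flanking diagonals at the split maximising matches (ties to the leftmost
split). Genomic gaps shorter than `min_intron_len` (20 bp) are absorbed
into a single exon; the absorbed exon's endpoints do not depend on the
internal split position, which keeps absorption exact. A model is
rejected (marker kept, model absent) when a transcript stretch longer
than `transcript_gap_tol` (30 bp) matches its assigned diagonal no better
than background (< 45% — random sequence matches at 25%, genuine
alignable sequence at >= 70%), e.g. a transcript insert absent from the
locus.

## Selection

Ranking modes: `exon_length` (total exon length), `exon_plus_intron`
(exon length + n_introns x round(mean intron length)), `variability`
(externally supplied per-marker fraction), `length_times_variability`.
The mean intron length is pooled over all candidates' models by default
(`mean_intron_scope: per_marker` switches to each marker's own mean);
using a mean rather than each marker's own introns avoids favouring
markers with occasional huge introns that may capture poorly. With no
introns anywhere the intron-aware modes degrade to exon-length ranking.

Selection is greedy first-fit-decreasing: walk the ranked list, take
every candidate whose bait requirement still fits the budget, skip those
that do not, and keep walking. This is deterministic, matches the
"longest sequences that fit" selection principle, and on random pools
stays within 10% of the exhaustive knapsack optimum in >= 90% of
instances (tested). Tiling places baits every `bait_len / coverage`
(30 bp) with the final bait right-aligned so every targetable base is
covered at least once; consequently the cumulative targeted exon length
exceeds `total_bait_len / coverage` by up to ~90 bp per exon (edge
effects), and the design reports both numbers — the conventional
footprint (`n_baits x bait_len / coverage`) and the exact targeted
length.

## Post-processing

Contig-to-target matches are removed to a rescue list when overlap
< 100 bp **or** identity < 75% (the two failure classes are rescued
separately, so the filter must be a disjunction). Contigs are placed on
target coordinates via their best hit (minus-strand contigs
reverse-complemented), and merged to fixpoint, longest overlap first,
ties by leftmost placement then contig ids — a deterministic schedule
that makes the result independent of input order. Two placed sequences
merge when they overlap by >= 30 bp with at most one irreconcilable
column; each merged column becomes the union of the observed base sets
(so successive conflicts accumulate into 2- and 3-base IUPAC codes), and
a column counts as a conflict only when the sets are disjoint — an `R`
meeting an `A` is consistent evidence, not a new difference. Rescue
fragments are attempted last and kept only if they join an anchored
sequence. Merging never invents a base: every output column is the IUPAC
code of bases actually observed there.

Variability: after removing columns with gaps or missing data in any
row, a column is variable iff the intersection of the ingroup rows' base
sets (IUPAC codes expanded) is empty. Cross-sample "alignment" of the
synthetic data is by shared target coordinates, which is exact for the
generator's substitution-only sequences; real data would be aligned
externally and supplied as a ready alignment. Merged sequences more
divergent than `paralog_split_identity` (0.90) can be segregated into
separate per-paralog matrices (`segregate_paralogs`).

## Synthetic data

The generator emulates the statistical structure of a bait-design study:
ancestral genes (3–6 exons of 150–500 bp, total >= 1,050 bp so every
transcript passes the 1,000 bp pre-filter; introns 60–400 bp), a genome
carrying the ancestral loci on a few scaffolds (either strand, random
spacers), and per-taxon transcriptomes derived by per-branch i.i.d.
substitutions at half the drawn pairwise divergence. Default composition
for 20 genes: 25% paralogous families (copies at 10% divergence, placed
on distinct scaffolds so the locus-counting rule sees them), 10% genes
private to one transcriptome, 10% homologue pairs at ~60% identity
(straddling the 75% capture floor), the rest shared single-copy at
5–20% pairwise divergence. The truth table records realised (counted)
identities, locus coordinates and structures; expected markers are
derived from it, not from the pipeline.

Two deliberate simplifications, and what they imply about the tests:

* **Substitution-only divergence.** Planted identities are exactly
  countable and exon alignments are gapless diagonals. Indel-rich real
  data would stress the banded extension and boundary refinement in ways
  these tests do not measure.
* **No splice signals.** Real exon boundaries are signposted by GT..AG
  motifs that the toolkit does not model. Instead the generator keeps a
  5 bp window flanking each junction substitution-free and forces the
  junction-adjacent intron bases to differ from the exon continuation,
  making the planted structure the unique optimum of the refinement's
  match-count criterion. Exact gene-model recovery therefore demonstrates
  correct chaining and boundary arithmetic, not splice-site detection;
  on real data boundary placement would be approximate wherever
  substitutions crowd a junction.

Capture simulation: per sample and target, the target is mutated at the
sample's divergence (2–8%), extended with random flanks (emulating
captured intron flanks), and cut into overlapping fragments (400–700 bp,
overlaps 50–90 bp; coverage gaps optional and off by default so that
sequence-count expectations are exact). Allele pairs differ at k
positions clustered in a 40 bp polymorphic patch; fragments either
contain the whole patch (emitted for both alleles) or none of it, so the
merge rule's outcome is determined: k = 1 collapses to one ambiguity-
coded sequence, k >= 2 keeps alleles apart. Some fragments are emitted
reverse-complemented to exercise strand handling.

## Problem sizes

The shipped tests and the acceptance script run the full pipeline on the
default 20-gene / 3-taxon study (~100 kb genome, ~70 transcripts), a
200-instance aligner-equivalence sweep on subjects up to 2 kb, 500 random
selection pools, and capture fixtures of 3–4 targets x 2–3 samples.
These sizes keep a complete run in minutes on one core; the pipeline
itself has no intrinsic size limit, but the exact DP oracle is quadratic
and intended for desk-scale verification, not genome-scale search.

## Known limitations

* Protein-space search is not implemented; the catalogue route compares
  nucleotide sequences at a relaxed floor (0.70), which keeps the
  decision structure but will miss homology only detectable in
  translation.
* No masking of low-complexity sequence and no e-values; the score floor
  substitutes for both at desk scale.
* The locus-merge rule cannot separate tandem duplicates closer than
  `locus_merge_gap`.
* Bait design ignores probe thermodynamics (GC content, melting
  temperature) and vendor-specific constraints.
* `variability` treats each merged sequence row independently; it does
  not phase alleles across markers.
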