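# baitkit

Custom ("made to measure") marker selection and bait design for targeted
sequence capture, aimed at phylogenomics of closely related species.

Universal probe kits trade breadth for information content: for a recently
radiated clade, markers designed against distant reference genomes are
short, over-conserved, and often not single copy in the focal group.
`baitkit` instead designs markers from the data closest to the study
group — two or more transcriptome assemblies of related taxa, ideally
complemented by a whole-genome (or genome-skim) assembly of one of them —
and selects the marker set that maximises recoverable sequence under a
fixed hybridisation-bait budget.

## What it does

**Stage 1 — discovery** (`baitkit.marker_discovery`)

1. drop transcripts shorter than 1,000 bp;
2. cluster cross-transcriptome homologues (connected components of
   reciprocal seeded local alignments);
3. call copy number — against the genome by counting distinct genomic
   loci of each cluster representative, or, without a genome, against a
   catalogue of reference genes classified single/mostly-single copy —
   and drop multi-copy clusters (paralogy confounds gene trees);
4. drop clusters whose minimum pairwise identity is below 75%: in-solution
   hybridisation between probe and target tolerates at most ~25%
   divergence;
5. infer each marker's exon/intron structure by spliced alignment of the
   transcript to its genomic locus.

**Stage 2 — selection** (`baitkit.marker_selection`)

Markers are ranked by total exon length, by predicted exon-plus-intron
length, or by (length x) variability, and selected greedily while the
design stays within the bait budget. With bait length `L = 120` bp and
tiling coverage `c = 4`, an exon of length `E >= L` needs

    n(E) = ceil((E - L) / (L / c)) + 1

baits (step `L/c = 30` bp, final bait right-aligned), and a budget of
`B = 5,770` baits gives a total bait length `B x L = 692,400` bp and a
capture footprint `B x L / c = 173,100` bp. Exons shorter than one bait
are never targeted, but a marker with at least one exon >= 120 bp stays
eligible — its short exons simply receive no probes. Ranking by predicted
length adds the **mean** intron length once per intron (rather than the
marker's own intron lengths) so that markers with unusually long introns
are not favoured.

**Post-processing** (`baitkit.capture_postprocess`)

Assembled contigs from a capture experiment are matched back to targets
(kept when they overlap a target by >= 100 bp at >= 75% identity; weaker
matches go to a rescue round), merged when their overlap (>= 30 bp) is
identical or differs at exactly one position — that position is recoded
with the IUPAC ambiguity code — and never merged otherwise, so paralogous
copies and divergent alleles stay separate. Alignment columns containing
gaps or missing data in any sample are excluded before the percentage of
variable sites per marker is computed.

**Supporting modules**: `homology_engine` (exact affine Smith–Waterman /
Needleman–Wunsch kernels plus a k-mer-seeded search that reproduces the
exact aligner's hits at the 75%-identity operating point),
`synthetic_data` (simulated genomes, transcriptomes, paralogs and capture
contigs with a complete truth table), `sequence_io` (FASTA/YAML/TSV/GFF3/
BED I/O and the run configuration), and a `baitkit` command-line
interface (`simulate`, `discover`, `select`, `postprocess`).

## Worked example

Simulate a study (20 ancestral genes, 3 taxa, a quarter of families
duplicated, homologue divergences straddling the 75% identity floor),
discover markers against the simulated genome, and select with the
intron-aware ranking:

```python
from baitkit import RunConfig
from baitkit.synthetic_data import SimParams, simulate_genome_and_transcriptomes
from baitkit.marker_discovery import discover_markers
from baitkit.marker_selection import mean_intron_length, select_markers, design_report

cfg = RunConfig()
genome, transcriptomes, truth = simulate_genome_and_transcriptomes(SimParams(seed=0))
candidates = discover_markers(transcriptomes, genome, None, cfg)
print(len(candidates), "candidate markers")     # 11 candidate markers
print(round(mean_intron_length(candidates), 1)) # 232.7  (bp, pooled mean)

cfg.rank_mode = "exon_plus_intron"
selected, design = select_markers(candidates, cfg)
print(design_report(design, selected).to_string(index=False))
```

```
         marker_id  n_exons_targeted  targetable_len predicted_len  n_baits
cluster_g17_taxon0                 6            2321          3486       62
cluster_g13_taxon0                 6            1951          3116       50
cluster_g11_taxon0                 6            1571          2736       38
...
             TOTAL                46           15723          <NA>      406
```

The 20 planted families resolve to exactly the 11 shared single-copy
genes above the identity floor (5 paralogous families, 2 taxon-private
genes and 2 over-divergent homologue pairs are rejected), each with its
planted exon/intron structure recovered exactly. All 11 fit the default
budget: 406 baits of 120 bp (48,720 bp of probes) targeting 15,723 bp of
exon sequence across 46 exons; `predicted_len` adds the pooled mean
intron length (233 bp) once per intron to estimate the final captured
span per marker.

The same pipeline from the shell:

```bash
baitkit simulate --preset discovery --seed 0 --out-dir fx/
baitkit discover --transcriptome fx/taxon0.fasta --transcriptome fx/taxon1.fasta \
    --transcriptome fx/taxon2.fasta --genome fx/genome.fasta --out-dir disc/
baitkit select --candidates disc/candidates.fasta --max-baits 5770 --out-dir sel/
```

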