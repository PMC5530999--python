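"""Synthetic genomes, transcriptomes and capture contigs with known truth.

The generator emulates the data a bait-design study starts from: a
whole-genome assembly of one reference taxon, transcriptomes of several
related taxa derived from common ancestral genes by per-branch
substitutions, paralogous gene duplications, taxon-private transcripts,
and homologue pairs too divergent for probe hybridisation.  For testing
the capture stage it fragments target sequences into overlapping contigs
with optional coverage gaps and planted allele pairs.

Divergence is substitution-only by default so that every planted identity
is exactly countable; the truth table records realised (counted)
identities, locus coordinates, exon/intron structures and allele
differences, against which the discovery and post-processing pipelines
are scored.

Real splice sites are signposted by conserved GT..AG-like motifs that the
toolkit deliberately does not model; instead the generator keeps a small
window flanking each exon/intron junction substitution-free and forces
the junction-adjacent intron bases to differ from the continuation of the
exon, which makes the planted gene structure the unique optimal spliced
alignment.  Passing gene-model tests therefore demonstrate correct chain
and boundary arithmetic, not splice-signal detection.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .sequence_io import RunConfig, SequenceRecord, revcomp

BASES = "ACGT"

CATEGORY_SINGLE = "single"
CATEGORY_PARALOG = "paralog"
CATEGORY_PRIVATE = "private"
CATEGORY_DIVERGED = "diverged"


@dataclass
class SimParams:
    """Generator settings; the defaults are the study conditions.

    20 ancestral genes across 3 taxa, pairwise transcript divergence of
    5–20% (comfortably inside the 75%-identity capture window), a quarter
    of gene families duplicated at 10% copy divergence, one in ten genes
    private to a single transcriptome and one in ten represented by
    homologues near 60% identity (outside the capture window).  Gene
    lengths are drawn so that every transcript passes the default 1,000 bp
    length pre-filter.
    """

    n_genes: int = 20
    n_taxa: int = 3
    exon_count_range: tuple[int, int] = (3, 6)
    exon_len_range: tuple[int, int] = (150, 500)
    min_total_exon_len: int = 1050
    intron_len_range: tuple[int, int] = (60, 400)
    divergence_range: tuple[float, float] = (0.05, 0.20)
    paralog_fraction: float = 0.25
    paralog_divergence: float = 0.10
    private_gene_fraction: float = 0.10
    diverged_fraction: float = 0.10
    diverged_pairwise_divergence: float = 0.45
    n_scaffolds: int = 3
    spacer_len_range: tuple[int, int] = (700, 1500)
    boundary_window: int = 5
    # capture simulation
    n_samples: int = 4
    sample_divergence_range: tuple[float, float] = (0.02, 0.08)
    contig_len_range: tuple[int, int] = (400, 700)
    contig_overlap_range: tuple[int, int] = (50, 90)
    contig_coverage_gap_prob: float = 0.0
    gap_len_range: tuple[int, int] = (20, 60)
    flank_len_range: tuple[int, int] = (0, 120)
    allele_prob: float = 0.5
    allele_diff_range: tuple[int, int] = (0, 3)
    allele_window: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("exon_count_range", "exon_len_range", "intron_len_range",
                     "spacer_len_range", "contig_len_range",
                     "contig_overlap_range", "flank_len_range",
                     "allele_diff_range", "gap_len_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValueError(f"invalid range {name}={lo, hi}")
        if self.exon_len_range[0] < 1:
            raise ValueError("exons must be at least 1 bp")
        for name in ("paralog_fraction", "private_gene_fraction",
                     "diverged_fraction", "allele_prob",
                     "contig_coverage_gap_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_taxa < 2:
            raise ValueError("need at least two taxa")
        if self.n_scaffolds < 2:
            raise ValueError("need at least two scaffolds (paralog copies "
                             "are placed on distinct scaffolds)")


@dataclass
class LocusTruth:
    """Genomic placement of one gene copy (forward-scaffold coordinates)."""

    copy: str
    scaffold: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]]
    introns: list[tuple[int, int]]

    @property
    def intron_lens(self) -> list[int]:
        return [e - s for s, e in self.introns]


@dataclass
class GeneTruth:
    family_id: str
    category: str
    copy_number: str  # single / multi
    loci: list[LocusTruth]
    # copy label -> taxon source -> transcript id (only emitted ones)
    transcripts: dict[str, dict[str, str]]
    # copy label -> {(taxon_i, taxon_j): realised identity}
    pairwise_identity: dict[str, dict[tuple[str, str], float]]

    def min_identity(self, copy: str = "a") -> float:
        vals = self.pairwise_identity.get(copy, {})
        return min(vals.values()) if vals else 1.0


@dataclass
class TruthTable:
    """Planted truth for a simulated discovery dataset."""

    genes: list[GeneTruth]
    params: SimParams

    def family_of_transcript(self, transcript_id: str) -> str | None:
        for g in self.genes:
            for per_taxon in g.transcripts.values():
                if transcript_id in per_taxon.values():
                    return g.family_id
        return None

    def expected_marker_families(self, cfg: RunConfig) -> set[str]:
        """Families a correct discovery run must emit under ``cfg``:
        single copy, shared by enough transcriptomes, and with minimum
        realised pairwise identity above the similarity floor."""
        out = set()
        for g in self.genes:
            if g.copy_number != "single":
                continue
            sources = set(g.transcripts.get("a", {}))
            if len(sources) < cfg.min_shared_transcriptomes:
                continue
            if g.min_identity("a") < cfg.min_identity:
                continue
            out.add(g.family_id)
        return out

    def locus_of(self, family_id: str, copy: str = "a") -> LocusTruth:
        for g in self.genes:
            if g.family_id == family_id:
                for locus in g.loci:
                    if locus.copy == copy:
                        return locus
        raise KeyError((family_id, copy))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.genes:
            for locus in g.loci:
                rows.append(
                    {
                        "family_id": g.family_id,
                        "category": g.category,
                        "copy_number": g.copy_number,
                        "copy": locus.copy,
                        "scaffold": locus.scaffold,
                        "strand": locus.strand,
                        "start": locus.start,
                        "end": locus.end,
                        "n_exons": len(locus.exons),
                        "intron_lens": ",".join(map(str, locus.intron_lens)),
                        "min_pairwise_identity": round(g.min_identity(locus.copy), 4),
                    }
                )
        return pd.DataFrame(rows)


# --------------------------------------------------------------------------


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


def _substitute(rng: np.random.Generator, seq: str, positions: np.ndarray) -> str:
    out = list(seq)
    for p in positions:
        old = BASES.index(out[p])
        out[p] = BASES[(old + 1 + rng.integers(0, 3)) % 4]
    return "".join(out)


def _mutate(
    rng: np.random.Generator, seq: str, rate: float, allowed: np.ndarray
) -> str:
    n_sub = min(int(round(rate * len(seq))), allowed.size)
    if n_sub == 0:
        return seq
    pos = rng.choice(allowed, size=n_sub, replace=False)
    return _substitute(rng, seq, pos)


def _counted_identity(a: str, b: str) -> float:
    assert len(a) == len(b)
    return sum(x == y for x, y in zip(a, b)) / len(a)


@dataclass
class _GeneDraft:
    family_id: str
    category: str
    exon_lens: list[int]
    intron_lens: list[int]
    exon_seqs: dict[str, list[str]]  # copy -> exon sequences
    intron_seqs: dict[str, list[str]]
    taxon_transcripts: dict[str, dict[str, str]]  # copy -> source -> seq

    def transcript(self, copy: str) -> str:
        return "".join(self.exon_seqs[copy])

    def genomic(self, copy: str) -> str:
        parts = []
        for i, ex in enumerate(self.exon_seqs[copy]):
            parts.append(ex)
            if i < len(self.intron_seqs[copy]):
                parts.append(self.intron_seqs[copy][i])
        return "".join(parts)


def _draw_gene_structure(rng: np.random.Generator, p: SimParams):
    k = int(rng.integers(p.exon_count_range[0], p.exon_count_range[1] + 1))
    exon_lens = list(
        map(int, rng.integers(p.exon_len_range[0], p.exon_len_range[1] + 1, k))
    )
    deficit = p.min_total_exon_len - sum(exon_lens)
    if deficit > 0:
        exon_lens[-1] += deficit
    intron_lens = list(
        map(int, rng.integers(p.intron_len_range[0], p.intron_len_range[1] + 1, k - 1))
    )
    return exon_lens, intron_lens


def _constrain_junctions(
    rng: np.random.Generator, exon_seqs: list[str], intron_seqs: list[str]
) -> list[str]:
    """Force junction-adjacent intron bases to differ from the exon
    continuation, so splice boundaries are uniquely recoverable."""
    fixed = []
    for i, intron in enumerate(intron_seqs):
        first_excl = exon_seqs[i + 1][0]
        last_excl = exon_seqs[i][-1]
        chars = list(intron)
        while chars[0] == first_excl:
            chars[0] = BASES[rng.integers(0, 4)]
        while chars[-1] == last_excl:
            chars[-1] = BASES[rng.integers(0, 4)]
        fixed.append("".join(chars))
    return fixed


def _mutable_transcript_positions(
    exon_lens: Sequence[int], window: int
) -> np.ndarray:
    """Transcript positions free to mutate: everything except ``window``
    bases on either side of each internal exon junction."""
    total = sum(exon_lens)
    blocked = np.zeros(total, dtype=bool)
    c = 0
    for length in exon_lens[:-1]:
        c += length
        blocked[max(0, c - window) : min(total, c + window)] = True
    return np.nonzero(~blocked)[0]


def _apply_exon_split(seq: str, exon_lens: Sequence[int]) -> list[str]:
    out = []
    c = 0
    for length in exon_lens:
        out.append(seq[c : c + length])
        c += length
    return out


def simulate_genome_and_transcriptomes(
    p: SimParams,
) -> tuple[list[SequenceRecord], list[list[SequenceRecord]], TruthTable]:
    """Build the reference genome, per-taxon transcriptomes and the truth.

    Returns ``(genome_records, transcriptomes, truth)`` where
    ``transcriptomes[t]`` holds the records of source ``taxon{t}``.
    All randomness flows from ``p.seed``.
    """
    rng = np.random.default_rng(p.seed)
    n_paralog = int(round(p.n_genes * p.paralog_fraction))
    n_private = int(round(p.n_genes * p.private_gene_fraction))
    n_diverged = int(round(p.n_genes * p.diverged_fraction))
    if n_paralog + n_private + n_diverged > p.n_genes:
        raise ValueError("category fractions exceed the gene count")
    categories = (
        [CATEGORY_PARALOG] * n_paralog
        + [CATEGORY_PRIVATE] * n_private
        + [CATEGORY_DIVERGED] * n_diverged
    )
    categories += [CATEGORY_SINGLE] * (p.n_genes - len(categories))

    taxa = [f"taxon{t}" for t in range(p.n_taxa)]
    drafts: list[_GeneDraft] = []
    for gi, category in enumerate(categories):
        family_id = f"g{gi:02d}"
        exon_lens, intron_lens = _draw_gene_structure(rng, p)
        exon_seqs_a = [_rand_seq(rng, n) for n in exon_lens]
        intron_seqs_a = _constrain_junctions(
            rng, exon_seqs_a, [_rand_seq(rng, n) for n in intron_lens]
        )
        exon_seqs = {"a": exon_seqs_a}
        intron_seqs = {"a": intron_seqs_a}
        if category == CATEGORY_PARALOG:
            mutable = _mutable_transcript_positions(exon_lens, p.boundary_window)
            tx_b = _mutate(rng, "".join(exon_seqs_a), p.paralog_divergence, mutable)
            exon_seqs_b = _apply_exon_split(tx_b, exon_lens)
            intron_seqs_b = []
            for intron in intron_seqs_a:
                if len(intron) > 2:
                    inner = np.arange(1, len(intron) - 1)
                    intron = _mutate(rng, intron, p.paralog_divergence, inner)
                intron_seqs_b.append(intron)
            intron_seqs_b = _constrain_junctions(rng, exon_seqs_b, intron_seqs_b)
            exon_seqs["b"] = exon_seqs_b
            intron_seqs["b"] = intron_seqs_b

        if category == CATEGORY_DIVERGED:
            pair_div = p.diverged_pairwise_divergence
        else:
            pair_div = float(rng.uniform(*p.divergence_range))
        branch = pair_div / 2.0

        mutable = _mutable_transcript_positions(exon_lens, p.boundary_window)
        taxon_transcripts: dict[str, dict[str, str]] = {}
        present = taxa[:1] if category == CATEGORY_PRIVATE else taxa
        for copy in exon_seqs:
            anc = "".join(exon_seqs[copy])
            taxon_transcripts[copy] = {
                taxon: _mutate(rng, anc, branch, mutable) for taxon in present
            }
        drafts.append(
            _GeneDraft(
                family_id=family_id,
                category=category,
                exon_lens=exon_lens,
                intron_lens=intron_lens,
                exon_seqs=exon_seqs,
                intron_seqs=intron_seqs,
                taxon_transcripts=taxon_transcripts,
            )
        )

    # --- scaffold assembly -------------------------------------------------
    scaffold_parts: list[list[tuple[str, str, str, str]]] = [
        [] for _ in range(p.n_scaffolds)
    ]  # (family, copy, strand, genomic seq)
    for draft in drafts:
        home = int(rng.integers(0, p.n_scaffolds))
        for copy in sorted(draft.exon_seqs):
            scaf = home
            if copy == "b":  # paralog copies on distinct scaffolds
                scaf = (home + 1 + int(rng.integers(0, p.n_scaffolds - 1))) % p.n_scaffolds
            strand = "+" if rng.random() < 0.5 else "-"
            scaffold_parts[scaf].append((draft.family_id, copy, strand, draft.genomic(copy)))

    genome_records: list[SequenceRecord] = []
    locus_truth: dict[tuple[str, str], LocusTruth] = {}
    for si, parts in enumerate(scaffold_parts):
        scaffold_id = f"scaffold{si}"
        chunks: list[str] = []
        offset = 0
        for family_id, copy, strand, gseq in parts:
            spacer = _rand_seq(rng, int(rng.integers(*p.spacer_len_range)))
            chunks.append(spacer)
            offset += len(spacer)
            insert = gseq if strand == "+" else revcomp(gseq)
            chunks.append(insert)
            draft = next(d for d in drafts if d.family_id == family_id)
            exons_local: list[tuple[int, int]] = []
            c = 0
            for i, length in enumerate(draft.exon_lens):
                exons_local.append((c, c + length))
                c += length
                if i < len(draft.intron_lens):
                    c += draft.intron_lens[i]
            gl = len(gseq)
            if strand == "+":
                exons = [(offset + s, offset + e) for s, e in exons_local]
            else:
                exons = sorted((offset + gl - e, offset + gl - s) for s, e in exons_local)
            introns = [
                (exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)
            ]
            locus_truth[(family_id, copy)] = LocusTruth(
                copy=copy, scaffold=scaffold_id, strand=strand,
                start=offset, end=offset + gl, exons=exons, introns=introns,
            )
            offset += gl
        chunks.append(_rand_seq(rng, int(rng.integers(*p.spacer_len_range))))
        genome_records.append(
            SequenceRecord(
                id=scaffold_id, source="genome",
                seq="".join(chunks), role="genomic",
            )
        )

    # --- transcriptome records and truth -----------------------------------
    transcriptomes: list[list[SequenceRecord]] = [[] for _ in taxa]
    genes: list[GeneTruth] = []
    for draft in drafts:
        tx_ids: dict[str, dict[str, str]] = {}
        pairwise: dict[str, dict[tuple[str, str], float]] = {}
        for copy, per_taxon in draft.taxon_transcripts.items():
            suffix = "" if len(draft.taxon_transcripts) == 1 else copy
            tx_ids[copy] = {}
            for taxon, seq in per_taxon.items():
                tid = f"{draft.family_id}{suffix}_{taxon}"
                tx_ids[copy][taxon] = tid
                transcriptomes[taxa.index(taxon)].append(
                    SequenceRecord(id=tid, source=taxon, seq=seq, role="transcript")
                )
            pairwise[copy] = {}
            names = sorted(per_taxon)
            for i in range(len(names)):
                for j in range(i + 1, len(names)):
                    pairwise[copy][(names[i], names[j])] = _counted_identity(
                        per_taxon[names[i]], per_taxon[names[j]]
                    )
        genes.append(
            GeneTruth(
                family_id=draft.family_id,
                category=draft.category,
                copy_number="multi" if draft.category == CATEGORY_PARALOG else "single",
                loci=[
                    locus_truth[(draft.family_id, copy)]
                    for copy in sorted(draft.exon_seqs)
                ],
                transcripts=tx_ids,
                pairwise_identity=pairwise,
            )
        )
    return genome_records, transcriptomes, TruthTable(genes=genes, params=p)


def build_catalogue(
    truth: TruthTable, transcriptomes: Sequence[Sequence[SequenceRecord]]
) -> list[SequenceRecord]:
    """Single-copy gene catalogue standing in for an angiosperm-wide
    classification: one reference coding sequence per family (the copy-a
    transcript of the first taxon carrying it), flagged single or multi
    copy according to the planted truth."""
    by_id = {r.id: r for recs in transcriptomes for r in recs}
    out = []
    for g in truth.genes:
        first_taxon = sorted(g.transcripts["a"])[0]
        rec = by_id[g.transcripts["a"][first_taxon]]
        flag = "multi" if g.copy_number == "multi" else "single"
        out.append(
            SequenceRecord(
                id=f"cat_{g.family_id}", source="catalogue", seq=rec.seq,
                role="target", description=flag,
            )
        )
    return out


# --------------------------------------------------------------------------
# capture contigs


@dataclass
class CaptureSampleTruth:
    target_id: str
    sample_id: str
    template_start: int  # target coordinate of the first template base
    template: str  # allele A, flanks included
    n_allele_diffs: int
    allele_positions: list[int]  # target coordinates
    n_gaps: int
    fragments: list[tuple[int, int, str]]  # (start, end, allele) target coords

    @property
    def expected_n_sequences(self) -> int:
        extra = 1 if self.n_allele_diffs >= 2 else 0
        return 1 + self.n_gaps + extra


@dataclass
class CaptureTruth:
    entries: list[CaptureSampleTruth]
    params: SimParams

    def entry(self, target_id: str, sample_id: str) -> CaptureSampleTruth:
        for e in self.entries:
            if (e.target_id, e.sample_id) == (target_id, sample_id):
                return e
        raise KeyError((target_id, sample_id))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "target_id": e.target_id,
                    "sample_id": e.sample_id,
                    "n_allele_diffs": e.n_allele_diffs,
                    "n_gaps": e.n_gaps,
                    "n_fragments": len(e.fragments),
                    "expected_n_sequences": e.expected_n_sequences,
                }
                for e in self.entries
            ]
        )


def simulate_capture_contigs(
    targets: Sequence[SequenceRecord], p: SimParams
) -> tuple[dict[str, list[SequenceRecord]], CaptureTruth]:
    """Fragment targets into per-sample contigs with planted polymorphism.

    Per sample and target, the target is first mutated at the sample's
    divergence and extended with flanking sequence (emulating captured
    intron flanks), then cut into overlapping fragments.  With probability
    ``allele_prob`` a second allele differing at ``allele_diff_range``
    positions (clustered inside a short window, as a polymorphic patch) is
    planted; fragments covering the window are emitted for both alleles.
    Coverage gaps are inserted with ``contig_coverage_gap_prob`` between
    consecutive fragments.
    """
    if not targets:
        raise ValueError("simulate_capture_contigs requires targets")
    rng = np.random.default_rng(p.seed + 1)
    samples = [f"sample{i}" for i in range(p.n_samples)]
    contigs: dict[str, list[SequenceRecord]] = {s: [] for s in samples}
    entries: list[CaptureSampleTruth] = []
    for target in targets:
        tlen = len(target.seq)
        for sample in samples:
            div = float(rng.uniform(*p.sample_divergence_range))
            base = _mutate(rng, target.seq, div, np.arange(tlen))
            fl = int(rng.integers(*_inc(p.flank_len_range)))
            fr = int(rng.integers(*_inc(p.flank_len_range)))
            template = _rand_seq(rng, fl) + base + _rand_seq(rng, fr)
            start = -fl

            k = 0
            positions: list[int] = []
            if rng.random() < p.allele_prob:
                k = int(rng.integers(*_inc(p.allele_diff_range)))
            window_lo = window_hi = 0
            template_b = template
            if k > 0:
                margin = 100
                w = min(p.allele_window, tlen - 2 * margin)
                lo = int(rng.integers(margin, tlen - margin - w + 1))
                window_lo, window_hi = lo, lo + w
                pos = rng.choice(np.arange(window_lo, window_hi), size=min(k, w),
                                 replace=False)
                positions = sorted(int(x) for x in pos)
                k = len(positions)
                template_b = _substitute(
                    rng, template, np.array([q - start for q in positions])
                )

            # fragment tiling over template coordinates
            frags: list[tuple[int, int]] = []
            n_gaps = 0
            c = start
            end_coord = start + len(template)
            while c < end_coord:
                flen = int(rng.integers(*_inc(p.contig_len_range)))
                f0, f1 = c, min(c + flen, end_coord)
                if k > 0 and f0 < window_hi and f1 > window_lo:
                    # fragments either contain the whole polymorphic patch
                    # or none of it
                    f0 = min(f0, window_lo - 5)
                    f1 = max(f1, window_hi + 5)
                    f0 = max(f0, start)
                    f1 = min(f1, end_coord)
                frags.append((f0, f1))
                if f1 >= end_coord:
                    break
                if rng.random() < p.contig_coverage_gap_prob:
                    gap = int(rng.integers(*_inc(p.gap_len_range)))
                    c = f1 + gap
                    if c < end_coord:
                        n_gaps += 1
                    else:
                        break
                else:
                    overlap = int(rng.integers(*_inc(p.contig_overlap_range)))
                    c = f1 - overlap

            frag_records: list[tuple[int, int, str]] = []
            for fi, (f0, f1) in enumerate(frags):
                seqs = [("A", template[f0 - start : f1 - start])]
                if k > 0 and f0 <= window_lo and f1 >= window_hi:
                    seqs.append(("B", template_b[f0 - start : f1 - start]))
                for allele, seq in seqs:
                    cid = f"{target.id}|{sample}|f{fi}" + ("b" if allele == "B" else "")
                    emit = seq
                    if rng.random() < 0.3:  # exercise minus-strand handling
                        emit = revcomp(seq)
                    contigs[sample].append(
                        SequenceRecord(id=cid, source=sample, seq=emit, role="contig")
                    )
                    frag_records.append((f0, f1, allele))
            entries.append(
                CaptureSampleTruth(
                    target_id=target.id,
                    sample_id=sample,
                    template_start=start,
                    template=template,
                    n_allele_diffs=k,
                    allele_positions=positions,
                    n_gaps=n_gaps,
                    fragments=frag_records,
                )
            )
    return contigs, CaptureTruth(entries=entries, params=p)


def _inc(rng_pair: tuple[int, int]) -> tuple[int, int]:
    """Half-open bounds for an inclusive integer range."""
    return rng_pair[0], rng_pair[1] + 1
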