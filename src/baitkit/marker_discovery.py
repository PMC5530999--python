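"""Stage 1: discover homologous single-copy marker candidates.

Given two or more transcriptome assemblies and optionally a whole-genome
assembly (or a single-copy gene catalogue when no genome is available),
this module

1. drops short transcripts (default < 1,000 bp),
2. clusters cross-transcriptome homologues by connected components of
   reciprocal local hits,
3. calls copy number per cluster (genomic locus counting, or catalogue
   lookup) and excludes multi-copy clusters,
4. applies the >=75% pairwise-identity filter (probe hybridisation
   tolerates at most 25% divergence), and
5. infers exon/intron structure by spliced mapping of the representative
   transcript onto its genomic locus.

The emitted :class:`MarkerCandidate` pool is the input to marker
selection (stage 2).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .homology_engine import (
    DEFAULT_SCORING,
    HomologyHit,
    Scoring,
    find_homologues,
    percent_identity,
)
from .sequence_io import RunConfig, SequenceRecord, revcomp

COPY_SINGLE = "single"
COPY_MULTI = "multi"
COPY_UNKNOWN = "unknown"

#: identity above which two same-source cluster members are treated as the
#: same transcript (isoform/assembly redundancy) rather than paralogs.
ISOFORM_IDENTITY = 0.99


@dataclass
class HomologueCluster:
    """A connected component of reciprocal cross-transcriptome hits."""

    cluster_id: str
    members: list[tuple[str, str]]  # (source, id)
    representative: tuple[str, str]
    min_pairwise_identity: float
    records: dict[tuple[str, str], SequenceRecord] = field(default_factory=dict)

    @property
    def n_sources(self) -> int:
        return len({src for src, _ in self.members})

    @property
    def representative_record(self) -> SequenceRecord:
        return self.records[self.representative]


@dataclass
class GeneModel:
    """Exon/intron structure of a transcript mapped onto its genomic locus.

    ``exons`` are forward-genome intervals sorted by genomic coordinate;
    ``t_intervals[i]`` is the transcript interval producing ``exons[i]``
    (for strand ``-`` these run antiparallel to the genome).  Genomic gaps
    shorter than the minimum intron length are absorbed into a single exon.
    """

    marker_id: str
    genome_id: str
    transcript_ref: tuple[str, str]
    exons: list[tuple[int, int]]
    introns: list[tuple[int, int]]
    strand: str
    t_intervals: list[tuple[int, int]]

    @property
    def exon_len_total(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def intron_lens(self) -> list[int]:
        return [e - s for s, e in self.introns]

    @property
    def n_introns(self) -> int:
        return len(self.introns)


@dataclass
class MarkerCandidate:
    """A transcript-anchored candidate marker that survived all filters."""

    marker_id: str
    cluster: HomologueCluster
    model: GeneModel | None
    copy_number: str
    identity_to_nearest_homologue: float
    exon_len_total: int
    n_introns: int
    seq: str
    predicted_len: int = 0

    @property
    def exon_t_intervals(self) -> list[tuple[int, int]]:
        """Transcript-side exon intervals (whole sequence when no model)."""
        if self.model is None:
            return [(0, len(self.seq))]
        return list(self.model.t_intervals)


# --------------------------------------------------------------------------


def prefilter_by_length(
    records: Sequence[SequenceRecord], min_len: int
) -> list[SequenceRecord]:
    """Keep records of length >= ``min_len`` (strictly shorter are removed)."""
    return [r for r in records if len(r) >= min_len]


class _UnionFind:
    def __init__(self):
        self.parent: dict = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def cluster_homologues(
    transcriptomes: Sequence[Sequence[SequenceRecord]],
    min_identity: float,
    min_hit_len: int,
    min_shared: int,
    scoring: Scoring = DEFAULT_SCORING,
    seed_len: int = 11,
    band: int = 15,
    min_score: int = 100,
) -> list[HomologueCluster]:
    """Cluster transcripts of different sources into homologue groups.

    Edges of the cluster graph are reciprocal :func:`find_homologues` hits
    between sequences of *different* sources at ``min_identity`` (the
    clustering floor is deliberately more permissive than the final
    similarity filter, so that divergent homologue groups are formed and
    then rejected explicitly) scoring at least ``min_score``.  The score
    floor matters on kilobase transcripts: chance local alignments between
    unrelated sequences can reach the identity/length floor but only at
    scores around 30, while genuine homologues share hundreds of score
    units.  Clusters covering fewer than ``min_shared`` sources are
    discarded.  ``min_pairwise_identity`` is the minimum global-alignment
    identity over all member pairs.
    """
    if len(transcriptomes) < 2:
        raise ValueError("cluster_homologues requires >= 2 transcriptome sources")
    by_key: dict[tuple[str, str], SequenceRecord] = {}
    for recs in transcriptomes:
        for r in recs:
            key = (r.source, r.id)
            if key in by_key:
                raise ValueError(f"duplicate record {key}")
            by_key[key] = r

    uf = _UnionFind()
    for key in sorted(by_key):
        uf.find(key)

    for (i, recs_a), (j, recs_b) in itertools.combinations(
        enumerate(transcriptomes), 2
    ):
        if not recs_a or not recs_b:
            continue
        ab = find_homologues(
            recs_a, recs_b, min_identity, min_hit_len,
            scoring=scoring, seed_len=seed_len, band=band,
        )
        ba = find_homologues(
            recs_b, recs_a, min_identity, min_hit_len,
            scoring=scoring, seed_len=seed_len, band=band,
        )
        fwd = {(h.query_id, h.subject_id) for h in ab if h.score >= min_score}
        rev = {(h.subject_id, h.query_id) for h in ba if h.score >= min_score}
        src_a = recs_a[0].source
        src_b = recs_b[0].source
        for qid, sid in fwd & rev:
            uf.union((src_a, qid), (src_b, sid))

    components: dict[tuple, list[tuple[str, str]]] = {}
    for key in sorted(by_key):
        components.setdefault(uf.find(key), []).append(key)

    clusters: list[HomologueCluster] = []
    for comp in components.values():
        sources = {src for src, _ in comp}
        if len(sources) < min_shared:
            continue
        members = sorted(comp)
        rep = max(members, key=lambda k: (len(by_key[k].seq), k[1]))
        # ties on length resolve to the lexicographically smallest id
        best_len = len(by_key[rep].seq)
        tied = [k for k in members if len(by_key[k].seq) == best_len]
        rep = min(tied, key=lambda k: (k[1], k[0]))
        min_pid = 1.0
        for ka, kb in itertools.combinations(members, 2):
            pid = percent_identity(by_key[ka].seq, by_key[kb].seq, scoring)
            min_pid = min(min_pid, pid)
        clusters.append(
            HomologueCluster(
                cluster_id=f"cluster_{rep[1]}",
                members=members,
                representative=rep,
                min_pairwise_identity=min_pid,
                records={k: by_key[k] for k in members},
            )
        )
    clusters.sort(key=lambda c: c.cluster_id)
    return clusters


# --------------------------------------------------------------------------
# copy number


def _chain_loci(
    hits: Sequence[HomologyHit], locus_merge_gap: int
) -> list[list[HomologyHit]]:
    """Group genomic hits of one query into loci.

    Hits on the same subject sequence and strand closer than
    ``locus_merge_gap`` on the genome belong to one locus (an intron-
    containing gene); larger gaps or different subjects are separate loci.
    """
    loci: list[list[HomologyHit]] = []
    keyed = sorted(hits, key=lambda h: (h.subject_id, h.strand, h.s_start))
    for (sid, strand), group in itertools.groupby(
        keyed, key=lambda h: (h.subject_id, h.strand)
    ):
        current: list[HomologyHit] = []
        end = None
        for h in group:
            if end is not None and h.s_start - end > locus_merge_gap:
                loci.append(current)
                current = []
            current.append(h)
            end = max(end, h.s_end) if end is not None else h.s_end
        if current:
            loci.append(current)
    return loci


def _locus_stats(locus: Sequence[HomologyHit], query_len: int) -> tuple[float, float]:
    """(chained identity, query coverage) of one locus."""
    matches = sum(h.matches for h in locus)
    aln = sum(h.aln_len for h in locus)
    intervals = sorted((h.q_start, h.q_end) for h in locus)
    covered = 0
    cur_s, cur_e = intervals[0]
    for s, e in intervals[1:]:
        if s > cur_e:
            covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    covered += cur_e - cur_s
    return matches / aln, covered / query_len


def catalogue_flag(record: SequenceRecord) -> str:
    """Copy-number flag of a catalogue entry, parsed from its description.

    Recognises the tokens ``single``, ``mostly_single`` and ``multi``; a
    catalogue entry without a flag counts as ``single`` (membership in a
    single-copy catalogue is itself the classification).
    """
    tokens = set(record.description.replace("=", " ").split())
    for flag in ("multi", "mostly_single", "single"):
        if flag in tokens:
            return flag
    return "single"


def call_copy_number(
    cluster: HomologueCluster,
    genome: Sequence[SequenceRecord] | None,
    catalogue: Sequence[SequenceRecord] | None,
    cfg: RunConfig,
) -> str:
    """Call a cluster single, multi or unknown copy.

    Route 1 (intra-source duplicates): a cluster holding two members from
    the same transcriptome that are < 99% identical to each other is a
    paralog group regardless of genomic evidence.

    Route 2 (WGS): map the representative onto the genome and count
    distinct loci with chained identity >= ``min_identity`` and query
    coverage >= ``min_locus_coverage``; one locus is single copy, two or
    more are multi.

    Route 3 (catalogue): single iff the best catalogue match (identity >=
    ``catalogue_min_identity``) is flagged single/mostly-single and the
    second-best match to a different entry scores < 0.9 x the best.
    """
    if genome is None and catalogue is None:
        raise ValueError("call_copy_number requires a genome or a catalogue")

    by_source: dict[str, list[tuple[str, str]]] = {}
    for key in cluster.members:
        by_source.setdefault(key[0], []).append(key)
    for keys in by_source.values():
        for ka, kb in itertools.combinations(keys, 2):
            pid = percent_identity(
                cluster.records[ka].seq, cluster.records[kb].seq
            )
            if pid < ISOFORM_IDENTITY:
                return COPY_MULTI

    rep = cluster.representative_record
    if genome is not None:
        hits = find_homologues(
            [rep], genome, cfg.min_identity, cfg.mapping_min_hit_len,
            seed_len=cfg.seed_len, band=cfg.band,
        )
        n_loci = 0
        for locus in _chain_loci(hits, cfg.locus_merge_gap):
            identity, coverage = _locus_stats(locus, len(rep))
            if identity >= cfg.min_identity and coverage >= cfg.min_locus_coverage:
                n_loci += 1
        if n_loci == 1:
            return COPY_SINGLE
        if n_loci >= 2:
            return COPY_MULTI
        if catalogue is None:
            return COPY_UNKNOWN

    assert catalogue is not None
    hits = find_homologues(
        [rep], catalogue, cfg.catalogue_min_identity, cfg.mapping_min_hit_len,
        seed_len=cfg.seed_len, band=cfg.band,
    )
    if not hits:
        return COPY_UNKNOWN
    best_per_entry: dict[str, float] = {}
    for h in hits:
        best_per_entry[h.subject_id] = max(
            best_per_entry.get(h.subject_id, 0.0), h.score
        )
    ranked = sorted(best_per_entry.items(), key=lambda kv: (-kv[1], kv[0]))
    best_id, best_score = ranked[0]
    flags = {r.id: catalogue_flag(r) for r in catalogue}
    if flags.get(best_id) not in ("single", "mostly_single"):
        return COPY_MULTI
    if len(ranked) > 1 and ranked[1][1] >= 0.9 * best_score:
        return COPY_MULTI
    return COPY_SINGLE


# --------------------------------------------------------------------------
# gene models


def _zone_unalignable(t_codes, g_codes, z0: int, z1: int, d: int) -> bool:
    """True when transcript[z0:z1] placed on genomic diagonal ``d`` matches
    no better than background (a genuinely unaligned stretch, e.g. a
    transcript insert absent from the locus)."""
    qa = t_codes[z0:z1]
    ga = g_codes[z0 + d : z1 + d]
    frac = ((qa == ga) & (qa < 4)).mean()
    return frac < 0.45


def infer_gene_model(
    transcript: SequenceRecord,
    genome: Sequence[SequenceRecord],
    cfg: RunConfig,
    marker_id: str | None = None,
) -> GeneModel | None:
    """Spliced map of a single-copy transcript onto its genomic locus.

    The maximal colinear chain of local hits (same scaffold and strand,
    monotone in both coordinate systems, selected by total matched bases,
    ties by leftmost genomic start) defines candidate exons.  Exon
    boundaries are then refined so that the exon set tiles the transcript:
    each unaligned transcript stretch between consecutive hits is split at
    the position maximising matches on the two flanking diagonals (ties to
    the leftmost split).  Genomic gaps shorter than ``cfg.min_intron_len``
    are absorbed into a single exon.  Returns ``None`` when more than
    ``cfg.transcript_gap_tol`` consecutive transcript bases cannot be
    aligned to the locus.
    """
    from . import _aligner

    marker_id = marker_id or transcript.id
    hits = find_homologues(
        [transcript], genome, cfg.min_identity, cfg.mapping_min_hit_len,
        seed_len=cfg.seed_len, band=cfg.band,
    )
    if not hits:
        return None
    loci = _chain_loci(hits, cfg.locus_merge_gap)
    loci.sort(
        key=lambda loc: (
            -sum(h.matches for h in loc),
            loc[0].subject_id,
            min(h.s_start for h in loc),
        )
    )
    locus = loci[0]
    scaffold_id = locus[0].subject_id
    strand = locus[0].strand
    scaffold = next(r for r in genome if r.id == scaffold_id)

    if strand == "-":
        work_t = SequenceRecord(
            id=transcript.id, source=transcript.source,
            seq=revcomp(transcript.seq), role=transcript.role,
        )
        hits = find_homologues(
            [work_t], [scaffold], cfg.min_identity, cfg.mapping_min_hit_len,
            seed_len=cfg.seed_len, band=cfg.band,
        )
        locus_hits = [h for h in hits if h.strand == "+"]
        if not locus_hits:
            return None
        # restrict to the locus region
        loci = _chain_loci(locus_hits, cfg.locus_merge_gap)
        loci.sort(key=lambda loc: (-sum(h.matches for h in loc),
                                   min(h.s_start for h in loc)))
        locus = loci[0]
    else:
        work_t = transcript
        locus = [h for h in locus if h.strand == "+"]
        if not locus:
            return None

    L = len(work_t.seq)
    t_codes = _aligner.encode(work_t.seq)
    g_codes = _aligner.encode(scaffold.seq)
    G = len(scaffold.seq)

    # maximal colinear chain by total matched bases (weighted LIS)
    cand = sorted(locus, key=lambda h: (h.q_start, h.s_start))
    slack = 80  # tolerated overlap between adjacent hits: local alignments
    # can overshoot an exon boundary by a short gapped sneak extension into
    # the intron; the boundary-refinement step resolves the overlap exactly
    n = len(cand)
    score = [h.matches for h in cand]
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            a, b = cand[j], cand[i]
            da = a.s_start - a.q_start
            db = b.s_start - b.q_start
            if (
                db >= da
                and b.q_start >= a.q_end - slack
                and b.s_start >= a.s_end - slack
                and score[j] + cand[i].matches > score[i]
            ):
                score[i] = score[j] + cand[i].matches
                prev[i] = j
    best = max(
        range(n), key=lambda i: (score[i], -cand[i].s_start)
    )
    chain: list[HomologyHit] = []
    k = best
    while k != -1:
        chain.append(cand[k])
        k = prev[k]
    chain.reverse()

    # explode chained hits into their gapless runs; drop short noise runs
    # (sneak extensions across exon boundaries) when longer runs exist
    min_run = 20
    runs: list[tuple[int, int, int]] = []
    for h in chain:
        long_runs = [r for r in h.segments if r[1] - r[0] >= min_run]
        runs.extend(long_runs if long_runs else h.segments)
    runs.sort(key=lambda r: (r[0], r[2]))
    # enforce diagonal monotonicity, dropping the shorter offender
    mono: list[tuple[int, int, int]] = []
    for r in runs:
        drop = False
        while mono and r[2] < mono[-1][2]:
            if r[1] - r[0] >= mono[-1][1] - mono[-1][0]:
                mono.pop()
            else:
                drop = True
                break
        if not drop:
            mono.append(r)
    # (q_start, q_end, diag, gapless runs backing the segment)
    merged: list[list] = []
    for q0, q1, d in mono:
        if merged and d == merged[-1][2]:
            merged[-1][1] = max(merged[-1][1], q1)
            merged[-1][3].append((q0, q1))
        else:
            merged.append([q0, q1, d, [(q0, q1)]])

    tol = cfg.transcript_gap_tol

    # refine: choose split points so exon q-intervals tile [0, L)
    bounds: list[int] = [0]
    for idx in range(len(merged) - 1):
        qa0, qa1, da, _runs_a = merged[idx]
        qb0, qb1, db, _runs_b = merged[idx + 1]
        if db < da:
            return None
        lo = max(bounds[-1] + 1, min(qa1, qb0) - 60)
        hi = min(L - 1, max(qa1, qb0) + 60, qb1)
        if lo > hi:
            lo = hi = max(bounds[-1] + 1, min(qb0, L - 1))
        best_t = lo
        best_m = -1
        for t in range(lo, hi + 1):
            m = 0
            for q in range(max(lo - 1, bounds[-1]), t):
                g = q + da
                if 0 <= g < G and t_codes[q] == g_codes[g] and t_codes[q] < 4:
                    m += 1
            for q in range(t, min(hi + 1, L)):
                g = q + db
                if 0 <= g < G and t_codes[q] == g_codes[g] and t_codes[q] < 4:
                    m += 1
            if m > best_m:
                best_m = m
                best_t = t
        bounds.append(best_t)
    bounds.append(L)

    segs: list[tuple[int, int, int]] = []  # (q0, q1, diag)
    for (q0, q1, d, runs), b0, b1 in zip(merged, bounds[:-1], bounds[1:]):
        if b1 <= b0:
            return None
        if b0 + d < 0 or b1 + d > G:
            return None
        # transcript stretches not backed by an alignment run were assigned
        # to this diagonal by extension; any such zone longer than the
        # tolerance must still match the locus, else the transcript does
        # not fully align (e.g. carries an insert) and the model is void
        cur = b0
        zones: list[tuple[int, int]] = []
        for r0, r1 in sorted(runs):
            r0, r1 = max(r0, b0), min(r1, b1)
            if r0 > cur:
                zones.append((cur, r0))
            cur = max(cur, r1)
        if cur < b1:
            zones.append((cur, b1))
        for z0, z1 in zones:
            if z1 - z0 > tol and _zone_unalignable(t_codes, g_codes, z0, z1, d):
                return None
        segs.append((b0, b1, d))

    # absorb sub-minimum genomic gaps into single exons
    exons: list[tuple[int, int]] = []
    t_intervals: list[tuple[int, int]] = []
    for q0, q1, d in segs:
        g0, g1 = q0 + d, q1 + d
        if exons and g0 - exons[-1][1] < cfg.min_intron_len:
            exons[-1] = (exons[-1][0], g1)
            t_intervals[-1] = (t_intervals[-1][0], q1)
        else:
            exons.append((g0, g1))
            t_intervals.append((q0, q1))
    introns = [
        (exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)
    ]

    if strand == "-":
        t_intervals = [(L - e, L - s) for s, e in t_intervals]

    return GeneModel(
        marker_id=marker_id,
        genome_id=scaffold_id,
        transcript_ref=(transcript.source, transcript.id),
        exons=exons,
        introns=introns,
        strand=strand,
        t_intervals=t_intervals,
    )


# --------------------------------------------------------------------------


def discover_markers(
    transcriptomes: Sequence[Sequence[SequenceRecord]],
    genome: Sequence[SequenceRecord] | None,
    catalogue: Sequence[SequenceRecord] | None,
    cfg: RunConfig,
) -> list[MarkerCandidate]:
    """Run the full stage-1 pipeline and return the candidate marker pool.

    Composition: length pre-filter -> homologue clustering -> copy-number
    calling (multi-copy excluded) -> pairwise-identity filter -> gene
    models.  Output is deterministic, ordered by marker id.
    """
    if genome is None and catalogue is None:
        raise ValueError("discover_markers requires a genome or a catalogue")
    filtered = [
        prefilter_by_length(recs, cfg.min_transcript_len) for recs in transcriptomes
    ]
    clusters = cluster_homologues(
        filtered,
        min_identity=cfg.cluster_min_identity,
        min_hit_len=cfg.min_hit_len,
        min_shared=cfg.min_shared_transcriptomes,
        seed_len=cfg.seed_len,
        band=cfg.band,
        min_score=cfg.cluster_min_score,
    )
    candidates: list[MarkerCandidate] = []
    for cluster in clusters:
        copy_number = call_copy_number(cluster, genome, catalogue, cfg)
        if copy_number != COPY_SINGLE:
            continue
        if cluster.min_pairwise_identity < cfg.min_identity:
            continue
        rep = cluster.representative_record
        nearest = max(
            (
                percent_identity(rep.seq, cluster.records[k].seq)
                for k in cluster.members
                if k != cluster.representative
            ),
            default=1.0,
        )
        model = (
            infer_gene_model(rep, genome, cfg, marker_id=cluster.cluster_id)
            if genome is not None
            else None
        )
        exon_len_total = model.exon_len_total if model else len(rep)
        n_introns = model.n_introns if model else 0
        candidates.append(
            MarkerCandidate(
                marker_id=cluster.cluster_id,
                cluster=cluster,
                model=model,
                copy_number=copy_number,
                identity_to_nearest_homologue=nearest,
                exon_len_total=exon_len_total,
                n_introns=n_introns,
                seq=rep.seq,
            )
        )
    candidates.sort(key=lambda c: c.marker_id)
    return candidates
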