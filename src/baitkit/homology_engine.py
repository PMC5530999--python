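"""Seeded local homology search with an exact aligner as ground truth.

This module fulfils the search contract that BLASTn provides in classical
bait-design pipelines: local nucleotide alignments between queries and
subjects (both strands) reported with percent identity, aligned spans and
strand.  Two routes exist on purpose:

* :func:`local_align` / :func:`percent_identity` run the exact dynamic
  programme — slow but optimal, the reference the heuristic is held to;
* :func:`find_homologues` seeds candidate regions with exact k-mer matches
  (default k=11), clusters seeds by diagonal, and runs the same exact DP
  inside a banded window around each cluster.  On desk-scale inputs every
  hit the exact aligner finds at >=75% identity is recovered.

Identity is matches / alignment columns (gaps included), the BLAST
convention.  Ns and IUPAC ambiguity codes count as mismatches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import _aligner
from .sequence_io import SequenceRecord, revcomp


@dataclass(frozen=True)
class Scoring:
    """Alignment scoring scheme (penalties as positive costs).

    A gap of length L costs ``gap_open + L * gap_extend``.
    """

    match: int = 1
    mismatch: int = -1
    gap_open: int = 2
    gap_extend: int = 1


DEFAULT_SCORING = Scoring()


@dataclass
class HomologyHit:
    """A local alignment between a query and a subject sequence.

    Coordinates are 0-based half-open; query coordinates are always on the
    forward query strand.  For strand ``-`` the subject interval refers to
    the forward subject sequence and the alignment pairs the query with its
    reverse complement.
    """

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    aln_len: int
    matches: int
    score: float
    gapopens: int = 0
    #: gapless runs of the alignment, (q_start, q_end, s - q diagonal);
    #: for strand "-" these refer to the reverse-complemented subject
    segments: list = field(default_factory=list)

    @property
    def identity(self) -> float:
        return self.matches / self.aln_len

    @property
    def q_span(self) -> int:
        return self.q_end - self.q_start

    @property
    def s_span(self) -> int:
        return self.s_end - self.s_start

    def __post_init__(self) -> None:
        if self.aln_len < max(self.q_span, self.s_span):
            raise ValueError("aln_len smaller than aligned span")
        if not (0 <= self.matches <= self.aln_len):
            raise ValueError("matches outside [0, aln_len]")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")


def local_align(a: str, b: str, scoring: Scoring = DEFAULT_SCORING) -> HomologyHit | None:
    """Optimal local alignment of ``a`` (query) against ``b`` (subject).

    Exact affine-gap Smith–Waterman; returns ``None`` when no positive-
    scoring local alignment exists.  Score ties resolve deterministically
    (smallest query end, then subject end).
    """
    if not a or not b:
        raise ValueError("local_align requires non-empty sequences")
    res = _aligner.sw_local(
        _aligner.encode(a), _aligner.encode(b),
        scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend,
    )
    if res is None:
        return None
    score, qs, qe, ss, se, aln_len, matches, gapopens, segments = res
    return HomologyHit(
        query_id="query", subject_id="subject",
        q_start=qs, q_end=qe, s_start=ss, s_end=se, strand="+",
        aln_len=aln_len, matches=matches, score=float(score),
        gapopens=gapopens, segments=segments,
    )


def percent_identity(a: str, b: str, scoring: Scoring = DEFAULT_SCORING) -> float:
    """Identity of the optimal global alignment (end gaps penalised).

    Defined as matches / alignment columns; used for the >=75% similarity
    filter applied to full-length candidate homologues.  The arguments are
    ordered canonically before aligning: when several optimal alignments
    tie in score they can differ slightly in column count, and identity
    must not depend on argument order.
    """
    if not a or not b:
        raise ValueError("percent_identity requires non-empty sequences")
    if (len(b), b) < (len(a), a):
        a, b = b, a
    _score, aln_len, matches = _aligner.nw_global(
        _aligner.encode(a), _aligner.encode(b),
        scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend,
    )
    return matches / aln_len


# --------------------------------------------------------------------------
# seeded search


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Integer code of each k-mer start position; -1 where any base is
    ambiguous."""
    n = codes.shape[0]
    if n < k:
        return np.empty(0, dtype=np.int64)
    valid = codes < 4
    out = np.zeros(n - k + 1, dtype=np.int64)
    ok = np.ones(n - k + 1, dtype=bool)
    for t in range(k):
        seg = codes[t : n - k + 1 + t].astype(np.int64)
        out = out * 4 + seg
        ok &= valid[t : n - k + 1 + t]
    out[~ok] = -1
    return out


class _SubjectIndex:
    """Sorted k-mer index over one subject strand."""

    def __init__(self, codes: np.ndarray, k: int):
        kmers = _kmer_codes(codes, k)
        order = np.argsort(kmers, kind="stable")
        self.sorted_kmers = kmers[order]
        self.positions = order.astype(np.int64)

    def lookup(self, query_kmers: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (query_pos, subject_pos) seed pairs."""
        lo = np.searchsorted(self.sorted_kmers, query_kmers, side="left")
        hi = np.searchsorted(self.sorted_kmers, query_kmers, side="right")
        counts = hi - lo
        keep = np.nonzero((query_kmers >= 0) & (counts > 0))[0]
        if keep.size == 0:
            return (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))
        qpos = np.repeat(keep, counts[keep])
        spos = np.concatenate([self.positions[lo[q] : hi[q]] for q in keep])
        return qpos, spos


def _cluster_seeds(
    qpos: np.ndarray,
    spos: np.ndarray,
    band: int,
    max_q_gap: int,
    primary: np.ndarray | None = None,
) -> list[tuple[int, int, int, int, int, int, int]]:
    """Group seeds into diagonal clusters.

    Returns tuples ``(q_min, q_max, s_min, s_max, d_min, d_max,
    n_primary, n_seeds, d_mode)`` where ``d_mode`` is the diagonal
    carrying the most seeds; a new cluster starts when the diagonal jumps
    by more than ``band`` or the query positions jump by more than
    ``max_q_gap``.  ``primary`` marks long (trusted) seeds; clusters of
    short paired seeds only are subject to an extra verification step.
    """
    if qpos.size == 0:
        return []
    if primary is None:
        primary = np.ones(qpos.size, dtype=bool)
    diag = spos - qpos
    order = np.lexsort((qpos, diag))
    d = diag[order]
    q = qpos[order]
    s = spos[order]
    p = primary[order].astype(np.int64)
    dd = np.diff(d)
    dq = np.diff(q)
    new_cluster = (dd > band) | ((dd == 0) & (dq > max_q_gap))
    starts = np.flatnonzero(np.concatenate(([True], new_cluster)))
    q_min = np.minimum.reduceat(q, starts)
    q_max = np.maximum.reduceat(q, starts)
    s_min = np.minimum.reduceat(s, starts)
    s_max = np.maximum.reduceat(s, starts)
    d_min = np.minimum.reduceat(d, starts)
    d_max = np.maximum.reduceat(d, starts)
    n_prim = np.add.reduceat(p, starts)
    ends = np.concatenate((starts[1:], [q.size]))
    out = []
    for i in range(starts.size):
        diags, counts = np.unique(d[starts[i] : ends[i]], return_counts=True)
        d_mode = int(diags[np.argmax(counts)])
        out.append(
            (int(q_min[i]), int(q_max[i]), int(s_min[i]), int(s_max[i]),
             int(d_min[i]), int(d_max[i]), int(n_prim[i]),
             int(ends[i] - starts[i]), d_mode)
        )
    return out


def _diagonal_support(
    q_codes: np.ndarray,
    s_codes: np.ndarray,
    q0: int,
    q1: int,
    d: int,
    pad: int = 50,
    win: int = 60,
    min_frac: float = 0.62,
) -> bool:
    """Cheap ungapped verification of a candidate diagonal: true when some
    ``win``-wide stretch around the seeds matches at >= ``min_frac``."""
    a0 = max(0, q0 - pad, -d)
    a1 = min(q_codes.shape[0], q1 + pad, s_codes.shape[0] - d)
    if a1 - a0 < 20:
        return False
    qa = q_codes[a0:a1]
    sa = s_codes[a0 + d : a1 + d]
    eq = ((qa == sa) & (qa < 4)).astype(np.int32)
    if eq.shape[0] <= win:
        return eq.mean() >= min_frac
    c = np.cumsum(eq)
    best = (c[win - 1 :] - np.concatenate([[0], c[:-win]])).max()
    return best >= min_frac * win


def _paired_seeds(
    qpos: np.ndarray, spos: np.ndarray, max_gap: int
) -> tuple[np.ndarray, np.ndarray]:
    """Short seeds that have a same-diagonal partner within ``max_gap``
    query positions.  Pairing suppresses the random-match noise a short
    seed length would otherwise admit, while catching divergent homologues
    that preserve no long exact word."""
    if qpos.size < 2:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    diag = spos - qpos
    order = np.lexsort((qpos, diag))
    dq, ds, dd = qpos[order], spos[order], diag[order]
    same = (dd[1:] == dd[:-1]) & (dq[1:] - dq[:-1] <= max_gap)
    keep = np.zeros(dq.size, dtype=bool)
    keep[1:] |= same
    keep[:-1] |= same
    return dq[keep], ds[keep]


def _dedup_hits(hits: list[HomologyHit]) -> list[HomologyHit]:
    """Drop hits largely contained in a higher-scoring hit of the same
    query/subject/strand."""
    hits = sorted(
        hits, key=lambda h: (h.query_id, -h.score, h.subject_id, h.q_start, h.s_start)
    )
    kept: list[HomologyHit] = []
    for h in hits:
        redundant = False
        for k in kept:
            if (h.query_id, h.subject_id, h.strand) != (k.query_id, k.subject_id, k.strand):
                continue
            q_ov = min(h.q_end, k.q_end) - max(h.q_start, k.q_start)
            s_ov = min(h.s_end, k.s_end) - max(h.s_start, k.s_start)
            if q_ov > 0.5 * h.q_span and s_ov > 0.5 * h.s_span:
                redundant = True
                break
        if not redundant:
            kept.append(h)
    return kept


def find_homologues(
    queries: Sequence[SequenceRecord],
    subjects: Sequence[SequenceRecord],
    min_identity: float,
    min_hit_len: int,
    scoring: Scoring = DEFAULT_SCORING,
    seed_len: int = 11,
    band: int = 15,
    pad: int = 400,
    max_q_gap: int = 2000,
    two_hit_seed_len: int = 7,
    two_hit_max_gap: int = 50,
) -> list[HomologyHit]:
    """All local hits with identity >= ``min_identity`` and aligned query
    span >= ``min_hit_len``, searching both subject strands.

    Candidate regions are seeded by exact ``seed_len``-mers plus paired
    ``two_hit_seed_len``-mers (two short seeds on one diagonal within
    ``two_hit_max_gap``, rescuing divergent homologues that preserve no
    long exact word), clustered by diagonal (clusters split when the
    diagonal moves by more than ``band``, so spliced exons yield separate
    hits), and each cluster is aligned with the exact banded DP inside a
    window padded by ``pad``.  Hits are sorted by (query_id, descending
    score).
    """
    if not queries or not subjects:
        raise ValueError("find_homologues requires non-empty inputs")

    subject_views = []  # (record, strand, codes, index, short index)
    for rec in subjects:
        fwd = _aligner.encode(rec.seq)
        rev = _aligner.encode(revcomp(rec.seq))
        for strand, codes in (("+", fwd), ("-", rev)):
            subject_views.append(
                (rec, strand, codes,
                 _SubjectIndex(codes, seed_len),
                 _SubjectIndex(codes, two_hit_seed_len))
            )

    hits: list[HomologyHit] = []
    for q in queries:
        q_codes = _aligner.encode(q.seq)
        q_kmers = _kmer_codes(q_codes, seed_len)
        q_kmers_short = _kmer_codes(q_codes, two_hit_seed_len)
        nq = len(q.seq)
        for rec, strand, s_codes, index, index_short in subject_views:
            qpos, spos = index.lookup(q_kmers)
            qpos2, spos2 = _paired_seeds(
                *index_short.lookup(q_kmers_short), two_hit_max_gap
            )
            primary = np.ones(qpos.size + qpos2.size, dtype=bool)
            primary[qpos.size:] = False
            if qpos2.size:
                qpos = np.concatenate([qpos, qpos2])
                spos = np.concatenate([spos, spos2])
            ms = s_codes.shape[0]
            for (q0s, q1s, s0s, s1s, dmin, dmax, n_primary, n_seeds,
                 d_mode) in _cluster_seeds(qpos, spos, band, max_q_gap, primary):
                # sparsely seeded clusters are usually chance word matches:
                # demand a matching stretch on the dominant diagonal before
                # paying for the DP (short-seed-only clusters also need a
                # third seed)
                if n_primary == 0 and n_seeds < 3:
                    continue
                if (n_primary == 0 or n_seeds < 5) and not _diagonal_support(
                    q_codes, s_codes, q0s, q1s + two_hit_seed_len, d_mode
                ):
                    continue
                w_q0 = max(0, q0s - pad)
                w_q1 = min(nq, q1s + seed_len + pad)
                w_s0 = max(0, s0s - pad)
                w_s1 = min(ms, s1s + seed_len + pad)
                shift = w_s0 - w_q0
                res = _aligner.sw_local(
                    q_codes[w_q0:w_q1],
                    s_codes[w_s0:w_s1],
                    scoring.match, scoring.mismatch,
                    scoring.gap_open, scoring.gap_extend,
                    dlo=dmin - shift - band,
                    dhi=dmax - shift + band,
                )
                if res is None:
                    continue
                score, qs, qe, ss, se, aln_len, matches, gapopens, segs = res
                qs += w_q0
                qe += w_q0
                ss += w_s0
                se += w_s0
                segs = [
                    (s0 + w_q0, s1 + w_q0, d + (w_s0 - w_q0)) for s0, s1, d in segs
                ]
                if qe - qs < min_hit_len:
                    continue
                if matches / aln_len < min_identity:
                    continue
                if strand == "-":
                    ss, se = ms - se, ms - ss
                hits.append(
                    HomologyHit(
                        query_id=q.id, subject_id=rec.id,
                        q_start=qs, q_end=qe, s_start=ss, s_end=se,
                        strand=strand, aln_len=aln_len, matches=matches,
                        score=float(score), gapopens=gapopens, segments=segs,
                    )
                )
    return _dedup_hits(hits)


def hits_to_table(hits: Iterable[HomologyHit]) -> pd.DataFrame:
    """Hits as a BLAST outfmt-6-style table (1-based inclusive coordinates)."""
    rows = []
    for h in hits:
        mismatch = h.aln_len - h.matches - (h.aln_len - max(h.q_span, h.s_span))
        rows.append(
            {
                "qseqid": h.query_id,
                "sseqid": h.subject_id,
                "pident": round(100.0 * h.identity, 2),
                "length": h.aln_len,
                "mismatch": mismatch,
                "gapopen": h.gapopens,
                "qstart": h.q_start + 1,
                "qend": h.q_end,
                "sstart": h.s_start + 1,
                "send": h.s_end,
                "score": h.score,
                "strand": h.strand,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
            "qstart", "qend", "sstart", "send", "score", "strand",
        ],
    )
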