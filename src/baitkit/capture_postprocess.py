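"""Post-processing of captured, assembled contigs into per-marker sequences.

Assembled contigs from a capture experiment are matched back to their
targets (contigs overlapping a target by < 100 bp or below 75% identity go
to a rescue list), placed on target coordinates, and merged: two contigs
combine only when they overlap by at least 30 bp and their overlapping
columns are identical or differ at exactly one column, in which case that
column is recoded with the IUPAC ambiguity code of the observed bases.
Contigs differing at two or more overlapping columns — typically distinct
alleles or paralogous copies — stay separate.  Finally, alignment columns
containing gaps or missing data in any sample are excluded and the
percentage of variable sites per marker is computed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio.Data.IUPACData import ambiguous_dna_values

from .homology_engine import DEFAULT_SCORING, Scoring, find_homologues, percent_identity
from .sequence_io import RunConfig, SequenceRecord, revcomp

#: frozenset of unambiguous bases -> IUPAC letter, e.g. {A, G} -> R
SET_TO_IUPAC: dict[frozenset, str] = {
    frozenset(bases): letter for letter, bases in ambiguous_dna_values.items()
}
IUPAC_TO_SET: dict[str, frozenset] = {
    letter: frozenset(bases) for letter, bases in ambiguous_dna_values.items()
}
IUPAC_TO_SET["?"] = frozenset("ACGT")

GAPLIKE = {"-", "N", "?"}


@dataclass
class ContigMatch:
    """Best-target assignment of one contig."""

    contig: SequenceRecord
    target_id: str
    overlap_len: int
    identity: float
    strand: str
    t_start: int
    t_end: int
    q_start: int
    q_end: int
    rescue: bool = False

    @property
    def sample_id(self) -> str:
        return self.contig.source


@dataclass
class MergedContigSet:
    """Merged per-target, per-sample sequences.

    One sequence means the marker resolved to a single copy; two suggest a
    pair of alleles; more than two, unresolved multi-copy capture.
    ``sequences`` holds ``(placement_start, seq)`` with placement on target
    coordinates (may be negative when a contig carries flanking sequence).
    """

    target_id: str
    sample_id: str
    sequences: list[tuple[int, str]]
    ambiguity_positions: list[tuple[int, int, str]]


@dataclass
class VariabilityReport:
    target_id: str
    aln_len_total: int
    aln_len_filtered: int
    n_variable: int

    @property
    def pct_variable(self) -> float:
        if self.aln_len_filtered == 0:
            return 0.0
        return self.n_variable / self.aln_len_filtered


# --------------------------------------------------------------------------


def match_contigs(
    contigs: Sequence[SequenceRecord],
    targets: Sequence[SequenceRecord],
    cfg: RunConfig,
    scoring: Scoring = DEFAULT_SCORING,
) -> list[ContigMatch]:
    """Assign each contig to its best-scoring target.

    Matches with target overlap >= ``cfg.min_target_overlap`` and identity
    >= ``cfg.min_identity`` are retained; weaker matches that still hit a
    target are kept on the rescue list (``rescue=True``) and attempted
    during merging after all retained contigs have been combined.  Contigs
    matching no target at all are dropped.
    """
    if not contigs or not targets:
        raise ValueError("match_contigs requires non-empty contigs and targets")
    hits = find_homologues(
        contigs, targets,
        min_identity=0.5, min_hit_len=20,
        scoring=scoring, seed_len=cfg.seed_len, band=cfg.band,
    )
    best: dict[str, list] = {}
    for h in hits:
        best.setdefault(h.query_id, []).append(h)
    matches: list[ContigMatch] = []
    by_id = {c.id: c for c in contigs}
    for cid in sorted(best):
        group = sorted(best[cid], key=lambda h: (-h.score, h.subject_id, h.s_start))
        h = group[0]
        overlap = h.s_end - h.s_start
        keep = overlap >= cfg.min_target_overlap and h.identity >= cfg.min_identity
        matches.append(
            ContigMatch(
                contig=by_id[cid],
                target_id=h.subject_id,
                overlap_len=overlap,
                identity=h.identity,
                strand=h.strand,
                t_start=h.s_start,
                t_end=h.s_end,
                q_start=h.q_start,
                q_end=h.q_end,
                rescue=not keep,
            )
        )
    return matches


# --------------------------------------------------------------------------
# merging

_Placed = tuple[int, list[frozenset], list[str]]  # start, base sets, contig ids


def _place(match: ContigMatch) -> _Placed:
    """Express a contig in target coordinates (reverse-complementing
    minus-strand contigs); assumes an essentially gapless placement."""
    seq = match.contig.seq
    if match.strand == "-":
        seq = revcomp(seq)
        q_start = len(seq) - match.q_end
    else:
        q_start = match.q_start
    start = match.t_start - q_start
    bases = [IUPAC_TO_SET.get(ch, frozenset()) for ch in seq]
    return start, bases, [match.contig.id]


def _conflicts(a: _Placed, b: _Placed) -> tuple[int, int]:
    """(overlap length, number of irreconcilable columns) of two placed
    sequences; a column conflicts when the base sets are disjoint."""
    lo = max(a[0], b[0])
    hi = min(a[0] + len(a[1]), b[0] + len(b[1]))
    if hi <= lo:
        return 0, 0
    conflicts = 0
    for pos in range(lo, hi):
        if not (a[1][pos - a[0]] & b[1][pos - b[0]]):
            conflicts += 1
    return hi - lo, conflicts


def _merge_pair(a: _Placed, b: _Placed) -> _Placed:
    lo = min(a[0], b[0])
    hi = max(a[0] + len(a[1]), b[0] + len(b[1]))
    bases: list[frozenset] = []
    for pos in range(lo, hi):
        sa = a[1][pos - a[0]] if a[0] <= pos < a[0] + len(a[1]) else None
        sb = b[1][pos - b[0]] if b[0] <= pos < b[0] + len(b[1]) else None
        if sa is not None and sb is not None:
            bases.append(sa | sb)
        else:
            bases.append(sa if sa is not None else sb)
    return lo, bases, sorted(a[2] + b[2])


def _merge_round(placed: list[_Placed], min_overlap: int) -> list[_Placed]:
    """Merge to fixpoint: longest-overlap pairs first, ties by leftmost
    placement, then by contig ids (making the result independent of input
    order)."""
    placed = sorted(placed, key=lambda p: (p[0], -len(p[1]), p[2]))
    while True:
        best_key = None
        best_pair = None
        for i, j in itertools.combinations(range(len(placed)), 2):
            overlap, conflicts = _conflicts(placed[i], placed[j])
            if overlap >= min_overlap and conflicts <= 1:
                key = (-overlap, min(placed[i][0], placed[j][0]),
                       placed[i][2], placed[j][2])
                if best_key is None or key < best_key:
                    best_key = key
                    best_pair = (i, j)
        if best_pair is None:
            return placed
        i, j = best_pair
        merged = _merge_pair(placed[i], placed[j])
        placed = [p for k, p in enumerate(placed) if k not in (i, j)]
        placed.append(merged)
        placed.sort(key=lambda p: (p[0], -len(p[1]), p[2]))


def merge_contigs(
    matches: Sequence[ContigMatch], cfg: RunConfig
) -> MergedContigSet:
    """Merge the contigs of one target and one sample.

    Retained contigs are merged to fixpoint first; rescue-listed fragments
    are then attempted under the same rules and kept only if they combine
    with an established sequence.  Merging never invents a base: each
    column of a merged sequence is the IUPAC code of the union of bases
    observed there.
    """
    if not matches:
        raise ValueError("merge_contigs requires at least one match")
    target_ids = {m.target_id for m in matches}
    sample_ids = {m.sample_id for m in matches}
    if len(target_ids) != 1 or len(sample_ids) != 1:
        raise ValueError("merge_contigs expects matches of one target and one sample")

    retained = [_place(m) for m in matches if not m.rescue]
    rescue = [_place(m) for m in matches if m.rescue]
    placed = _merge_round(retained, cfg.min_merge_overlap) if retained else []

    if rescue:
        anchored_ids = {cid for p in placed for cid in p[2]}
        with_rescue = _merge_round(placed + rescue, cfg.min_merge_overlap)
        placed = [
            p for p in with_rescue
            if set(p[2]) & anchored_ids or not anchored_ids
        ]

    placed.sort(key=lambda p: (p[0], -len(p[1]), p[2]))
    sequences: list[tuple[int, str]] = []
    ambiguity: list[tuple[int, int, str]] = []
    for seq_idx, (start, bases, _ids) in enumerate(placed):
        letters = []
        for pos, s in enumerate(bases):
            letter = SET_TO_IUPAC.get(s, "N")
            letters.append(letter)
            if len(s) >= 2:
                ambiguity.append((seq_idx, pos, letter))
        sequences.append((start, "".join(letters)))
    return MergedContigSet(
        target_id=next(iter(target_ids)),
        sample_id=next(iter(sample_ids)),
        sequences=sequences,
        ambiguity_positions=ambiguity,
    )


# --------------------------------------------------------------------------
# alignment statistics


def filter_alignment_columns(alignment: Sequence[str]) -> list[str]:
    """Remove columns containing a gap (-) or missing base (N/?) in any row."""
    if not alignment:
        return []
    length = len(alignment[0])
    if any(len(row) != length for row in alignment):
        raise ValueError("alignment rows must have equal length")
    keep = [
        col for col in range(length)
        if all(row[col] not in GAPLIKE for row in alignment)
    ]
    return ["".join(row[col] for col in keep) for row in alignment]


def variability(
    alignment: Mapping[str, str],
    ingroup: Sequence[str],
    target_id: str = "",
    aln_len_total: int | None = None,
) -> VariabilityReport:
    """Percentage of variable sites among ingroup rows of a filtered
    alignment.

    A column is variable iff the base sets of the ingroup rows (IUPAC
    codes expanded) cannot be reconciled, i.e. their intersection is
    empty; a column like {A, R} is *not* variable because R contains A.
    """
    if len(ingroup) < 2:
        raise ValueError("variability requires >= 2 ingroup rows")
    rows = [alignment[k] for k in ingroup]
    length = len(rows[0])
    if any(len(r) != length for r in rows):
        raise ValueError("alignment rows must have equal length")
    n_variable = 0
    for col in range(length):
        sets = [IUPAC_TO_SET.get(row[col], frozenset()) for row in rows]
        inter = frozenset("ACGT")
        for s in sets:
            inter = inter & s
        if not inter:
            n_variable += 1
    return VariabilityReport(
        target_id=target_id,
        aln_len_total=aln_len_total if aln_len_total is not None else length,
        aln_len_filtered=length,
        n_variable=n_variable,
    )


def coordinate_alignment(
    merged: Mapping[str, MergedContigSet], span: tuple[int, int]
) -> dict[str, str]:
    """Stack per-sample merged sequences into a coordinate-based alignment.

    Valid for sequences already expressed on shared target coordinates
    (the synthetic generator's substitution-only data); positions outside a
    sequence's coverage are filled with ``N`` and removed by column
    filtering.  Samples with several sequences contribute one row each
    (``sample/0``, ``sample/1``, ...); single-sequence samples contribute
    row ``sample``.
    """
    lo, hi = span
    out: dict[str, str] = {}
    for sample in sorted(merged):
        mset = merged[sample]
        for idx, (start, seq) in enumerate(mset.sequences):
            row = []
            for pos in range(lo, hi):
                p = pos - start
                row.append(seq[p] if 0 <= p < len(seq) else "N")
            key = sample if len(mset.sequences) == 1 else f"{sample}/{idx}"
            out[key] = "".join(row)
    return out


def segregate_paralogs(
    sequences: Sequence[tuple[str, str]], min_identity: float
) -> list[list[str]]:
    """Group sequence ids into putative homolog matrices by single-linkage
    at ``min_identity`` global identity; divergent copies (paralogs) fall
    into separate groups."""
    ids = [sid for sid, _ in sequences]
    seqs = dict(sequences)
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (ia, sa), (ib, sb) in itertools.combinations(sequences, 2):
        if percent_identity(sa, sb) >= min_identity:
            ra, rb = find(ia), find(ib)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
    groups: dict[str, list[str]] = {}
    for i in ids:
        groups.setdefault(find(i), []).append(i)
    return [sorted(g) for _, g in sorted(groups.items())]
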