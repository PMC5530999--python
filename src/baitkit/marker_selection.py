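"""Stage 2: select an optimal marker set under a fixed bait budget.

Candidates from stage 1 are ranked — by total exon length, by predicted
exon-plus-intron length (using the mean intron length so that markers
with unusually large introns are not favoured), by an externally supplied
variability score, or by length x variability — and the longest-ranked
markers are selected greedily while the cumulative number of 120 bp baits
stays within the budget (default 5,770 baits at 4x tiling, i.e. a total
bait length of 692,400 bp).  Exons shorter than one bait are never
targeted, but their markers stay eligible through their longer exons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .marker_discovery import MarkerCandidate
from .sequence_io import RunConfig


@dataclass
class RankedCandidate:
    candidate: MarkerCandidate
    targetable_exon_len: int
    predicted_len: int
    rank_score: float
    n_baits_needed: int

    @property
    def marker_id(self) -> str:
        return self.candidate.marker_id


@dataclass
class BaitDesign:
    """Tiled probe layout and footprint accounting for a selected set.

    ``baits`` entries are ``(marker_id, exon_index, start, end)`` with
    coordinates on the marker's target (transcript) sequence and
    ``end - start == bait_len``.  ``footprint`` is the cumulative targeted
    exon length; ``nominal_footprint`` is total bait length divided by the
    tiling coverage (the conventional "capture footprint" number, exact
    only up to tiling edge effects on short exons).
    """

    marker_ids: list[str]
    baits: list[tuple[str, int, int, int]]
    bait_len: int
    coverage: int
    footprint: int

    @property
    def n_baits(self) -> int:
        return len(self.baits)

    @property
    def total_bait_len(self) -> int:
        return self.n_baits * self.bait_len

    @property
    def nominal_footprint(self) -> int:
        return self.total_bait_len // self.coverage


def mean_intron_length(candidates: Sequence[MarkerCandidate]) -> float:
    """Arithmetic mean of all intron lengths pooled across gene models."""
    pooled: list[int] = []
    for c in candidates:
        if c.model is not None:
            pooled.extend(c.model.intron_lens)
    if not pooled:
        raise ValueError(
            "no candidate carries an intron; rank with rank_mode=exon_length"
        )
    return sum(pooled) / len(pooled)


def predict_marker_length(
    c: MarkerCandidate, mu_intron: float, mode: str
) -> int:
    """Predicted capture length of a marker.

    ``exon_length`` ignores introns entirely; ``exon_plus_intron`` adds the
    (rounded) mean intron length once per intron, deliberately not the
    marker's own intron lengths, to avoid favouring large-intron markers.
    """
    if mode == "exon_length":
        return c.exon_len_total
    if mode == "exon_plus_intron":
        return c.exon_len_total + c.n_introns * round(mu_intron)
    raise ValueError(f"no length prediction for mode {mode!r}")


def tile_baits(exon_len: int, bait_len: int, coverage: int) -> tuple[int, list[int]]:
    """Number of baits and their offsets tiling one exon.

    Baits step by ``bait_len / coverage``; the final bait is right-aligned
    to end exactly at ``exon_len`` so every targetable base is covered.
    """
    if bait_len % coverage != 0:
        raise ValueError("bait_len must be divisible by coverage")
    if exon_len < bait_len:
        raise ValueError(
            f"exon of {exon_len} bp is shorter than one bait ({bait_len} bp)"
        )
    step = bait_len // coverage
    count = math.ceil((exon_len - bait_len) / step) + 1
    offsets = [i * step for i in range(count - 1)]
    offsets.append(exon_len - bait_len)
    return count, offsets


def _targetable_exons(
    c: MarkerCandidate, min_exon_len: int
) -> list[tuple[int, tuple[int, int]]]:
    """(exon_index, transcript interval) of exons long enough to target."""
    out = []
    for idx, (s, e) in enumerate(c.exon_t_intervals):
        if e - s >= min_exon_len:
            out.append((idx, (s, e)))
    return out


def rank_candidates(
    candidates: Sequence[MarkerCandidate],
    cfg: RunConfig,
    variability: Mapping[str, float] | None = None,
) -> list[RankedCandidate]:
    """Score candidates under ``cfg.rank_mode`` and sort them.

    Candidates whose every exon is shorter than ``cfg.min_exon_len`` are
    dropped (nothing can be targeted).  Sort order: descending score, then
    fewer baits needed, then lexicographic marker id.
    """
    mode = cfg.rank_mode
    if mode in ("variability", "length_times_variability") and variability is None:
        raise ValueError(f"rank_mode {mode!r} requires a variability map")

    needs_mu = mode in ("exon_plus_intron", "length_times_variability")
    have_introns = any(c.n_introns > 0 for c in candidates)
    # with no introns anywhere the intron-aware modes degrade gracefully
    # to exon-length ranking (mu = 0)
    mu = mean_intron_length(candidates) if needs_mu and have_introns else 0.0
    if cfg.mean_intron_scope == "per_marker":
        global_mu = mu

    ranked: list[RankedCandidate] = []
    for c in candidates:
        exons = _targetable_exons(c, cfg.min_exon_len)
        if not exons:
            continue
        targetable = sum(e - s for _, (s, e) in exons)
        n_baits = sum(
            tile_baits(e - s, cfg.bait_len, cfg.tiling_coverage)[0]
            for _, (s, e) in exons
        )
        c_mu = mu
        if cfg.mean_intron_scope == "per_marker" and needs_mu:
            own = c.model.intron_lens if c.model else []
            c_mu = sum(own) / len(own) if own else global_mu
        if mode == "exon_length":
            predicted = predict_marker_length(c, c_mu, "exon_length")
            score = float(predicted)
        elif mode == "exon_plus_intron":
            predicted = predict_marker_length(c, c_mu, "exon_plus_intron")
            score = float(predicted)
        elif mode == "variability":
            predicted = c.exon_len_total
            score = float(variability.get(c.marker_id, 0.0))
        else:  # length_times_variability
            pmode = "exon_plus_intron" if c.n_introns else "exon_length"
            predicted = predict_marker_length(c, c_mu, pmode)
            score = predicted * float(variability.get(c.marker_id, 0.0))
        c.predicted_len = predicted
        ranked.append(
            RankedCandidate(
                candidate=c,
                targetable_exon_len=targetable,
                predicted_len=predicted,
                rank_score=score,
                n_baits_needed=n_baits,
            )
        )
    ranked.sort(key=lambda r: (-r.rank_score, r.n_baits_needed, r.marker_id))
    return ranked


def select_markers(
    candidates: Sequence[MarkerCandidate],
    cfg: RunConfig,
    variability: Mapping[str, float] | None = None,
) -> tuple[list[RankedCandidate], BaitDesign]:
    """Greedy first-fit-decreasing selection under the bait budget.

    Walk the ranked list, adding each candidate whose bait requirement
    still fits within ``cfg.max_baits``; candidates that do not fit are
    skipped and the walk continues (a smaller marker further down may
    still fit).  Returns the selected candidates and the tiled design.
    """
    if not candidates:
        raise ValueError("select_markers requires at least one candidate")
    ranked = rank_candidates(candidates, cfg, variability)
    selected: list[RankedCandidate] = []
    used = 0
    for r in ranked:
        if used + r.n_baits_needed <= cfg.max_baits:
            selected.append(r)
            used += r.n_baits_needed
    baits: list[tuple[str, int, int, int]] = []
    footprint = 0
    for r in selected:
        for exon_idx, (s, e) in _targetable_exons(r.candidate, cfg.min_exon_len):
            _, offsets = tile_baits(e - s, cfg.bait_len, cfg.tiling_coverage)
            footprint += e - s
            for off in offsets:
                baits.append((r.marker_id, exon_idx, s + off, s + off + cfg.bait_len))
    design = BaitDesign(
        marker_ids=[r.marker_id for r in selected],
        baits=baits,
        bait_len=cfg.bait_len,
        coverage=cfg.tiling_coverage,
        footprint=footprint,
    )
    assert design.n_baits <= cfg.max_baits
    return selected, design


def design_report(
    design: BaitDesign, selected: Sequence[RankedCandidate] | None = None
) -> pd.DataFrame:
    """Per-marker summary plus a TOTAL row.

    The TOTAL row carries the headline accounting: number of baits, total
    bait length (n x bait length) and the capture footprints (cumulative
    targeted exon length, and total bait length / coverage).
    """
    per_marker: dict[str, dict] = {}
    for marker_id, exon_idx, s, e in design.baits:
        row = per_marker.setdefault(
            marker_id,
            {"marker_id": marker_id, "n_exons_targeted": set(), "n_baits": 0},
        )
        row["n_exons_targeted"].add(exon_idx)
        row["n_baits"] += 1
    info = {r.marker_id: r for r in selected} if selected else {}
    rows = []
    for marker_id in design.marker_ids:
        row = per_marker.get(
            marker_id,
            {"marker_id": marker_id, "n_exons_targeted": set(), "n_baits": 0},
        )
        r = info.get(marker_id)
        rows.append(
            {
                "marker_id": marker_id,
                "n_exons_targeted": len(row["n_exons_targeted"]),
                "targetable_len": r.targetable_exon_len if r else pd.NA,
                "predicted_len": r.predicted_len if r else pd.NA,
                "n_baits": row["n_baits"],
            }
        )
    rows.append(
        {
            "marker_id": "TOTAL",
            "n_exons_targeted": sum(r["n_exons_targeted"] for r in rows) if rows else 0,
            "targetable_len": design.footprint,
            "predicted_len": pd.NA,
            "n_baits": design.n_baits,
        }
    )
    df = pd.DataFrame(rows)
    df.attrs["total_bait_len"] = design.total_bait_len
    df.attrs["capture_footprint"] = design.nominal_footprint
    df.attrs["targeted_exon_len"] = design.footprint
    return df


def knapsack_optimum(
    items: Sequence[tuple[int, int]], budget: int
) -> int:
    """Exhaustive 0/1-knapsack optimum (value maximised under a bait
    budget); test oracle for bounding the greedy rule on tiny instances."""
    best = 0
    n = len(items)
    if n > 20:
        raise ValueError("exhaustive oracle is for tiny instances only")
    for mask in range(1 << n):
        cost = value = 0
        for i in range(n):
            if mask >> i & 1:
                cost += items[i][0]
                value += items[i][1]
        if cost <= budget and value > best:
            best = value
    return best
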