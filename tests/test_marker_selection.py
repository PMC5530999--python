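import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from baitkit.marker_discovery import GeneModel, MarkerCandidate
from baitkit.marker_selection import (
    BaitDesign,
    design_report,
    knapsack_optimum,
    mean_intron_length,
    predict_marker_length,
    rank_candidates,
    select_markers,
    tile_baits,
)
from baitkit.sequence_io import RunConfig


def make_candidate(mid, exon_lens, intron_lens=(), seq_char="A"):
    """Candidate with the given exon/intron structure (synthetic model)."""
    assert len(intron_lens) in (0, len(exon_lens) - 1)
    t_intervals = []
    exons = []
    q = 0
    g = 1000
    for i, n in enumerate(exon_lens):
        t_intervals.append((q, q + n))
        exons.append((g, g + n))
        q += n
        g += n
        if i < len(exon_lens) - 1:
            g += intron_lens[i] if intron_lens else 200
    introns = [(exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)]
    model = None
    if len(exon_lens) > 1 or intron_lens:
        model = GeneModel(
            marker_id=mid, genome_id="scaf", transcript_ref=("t", mid),
            exons=exons, introns=introns, strand="+", t_intervals=t_intervals,
        )
    total = sum(exon_lens)
    return MarkerCandidate(
        marker_id=mid, cluster=None, model=model, copy_number="single",
        identity_to_nearest_homologue=1.0, exon_len_total=total,
        n_introns=len(introns) if model else 0, seq=seq_char * total,
    )


class TestMeanIntronLength:
    def test_pooled_mean_across_models(self):
        c1 = make_candidate("m1", [500, 600, 700], [100, 300])
        c2 = make_candidate("m2", [800, 900], [200])
        assert mean_intron_length([c1, c2]) == 200

    def test_single_intron(self):
        assert mean_intron_length([make_candidate("m", [500, 500], [123])]) == 123

    def test_no_introns_is_an_error(self):
        with pytest.raises(ValueError, match="exon_length"):
            mean_intron_length([make_candidate("m", [1000])])


class TestPredictMarkerLength:
    def test_exon_plus_intron_uses_rounded_mean(self):
        c = make_candidate("m", [700, 700, 600], [100, 100])
        assert c.n_introns == 2
        assert predict_marker_length(c, 400.0, "exon_plus_intron") == 2800
        assert predict_marker_length(c, 400.4, "exon_plus_intron") == 2800

    def test_zero_introns_predicts_exon_total_in_both_modes(self):
        c = make_candidate("m", [1500])
        assert predict_marker_length(c, 400.0, "exon_length") == 1500
        assert predict_marker_length(c, 400.0, "exon_plus_intron") == 1500

    def test_exon_length_mode_ignores_introns(self):
        c = make_candidate("m", [700, 800], [5000])
        assert predict_marker_length(c, 5000.0, "exon_length") == 1500


class TestTileBaits:
    @pytest.mark.parametrize(
        "exon_len,expect_n,expect_offsets",
        [
            (120, 1, [0]),
            (150, 2, [0, 30]),
            (135, 2, [0, 15]),
            (180, 3, [0, 30, 60]),
            (190, 4, [0, 30, 60, 70]),
        ],
    )
    def test_tiling_with_right_aligned_final_bait(self, exon_len, expect_n, expect_offsets):
        n, offsets = tile_baits(exon_len, 120, 4)
        assert n == expect_n
        assert offsets == expect_offsets
        assert offsets[-1] + 120 == exon_len

    def test_exon_shorter_than_bait_is_an_error(self):
        with pytest.raises(ValueError):
            tile_baits(119, 120, 4)


class TestSelectMarkers:
    def test_greedy_first_fit_decreasing_trace(self):
        # budget 10 baits; candidates needing [6, 5, 4] baits with scores
        # [270, 240, 210]: the second does not fit and is skipped, the
        # third still fits
        cfg = RunConfig(max_baits=10)
        candidates = [
            make_candidate("m1", [270]),
            make_candidate("m2", [240]),
            make_candidate("m3", [210]),
        ]
        selected, design = select_markers(candidates, cfg)
        assert [r.n_baits_needed for r in selected] == [6, 4]
        assert design.marker_ids == ["m1", "m3"]
        assert design.n_baits == 10

    def test_marker_with_only_short_exons_is_dropped(self):
        cfg = RunConfig(max_baits=100)
        short = make_candidate("short", [80, 90, 60], [100, 100])
        ok = make_candidate("ok", [200, 80, 300], [100, 100])
        selected, design = select_markers([short, ok], cfg)
        assert design.marker_ids == ["ok"]

    def test_sub_bait_exon_untargeted_but_marker_retained(self):
        cfg = RunConfig(max_baits=100)
        c = make_candidate("mix", [200, 80, 300], [100, 100])
        (r,), design = select_markers([c], cfg)
        assert r.targetable_exon_len == 500
        assert r.candidate.exon_len_total == 580
        targeted_exons = {b[1] for b in design.baits}
        assert targeted_exons == {0, 2}
        assert design.footprint == 500

    def test_variability_mode_requires_map(self):
        cfg = RunConfig(max_baits=100, rank_mode="variability")
        with pytest.raises(ValueError, match="variability"):
            select_markers([make_candidate("m", [500])], cfg)

    def test_variability_mode_ranks_by_supplied_fraction(self):
        cfg = RunConfig(max_baits=18, rank_mode="variability")
        a = make_candidate("a", [600])  # 17 baits
        b = make_candidate("b", [240])  # 5 baits
        selected, design = select_markers(
            [a, b], cfg, variability={"a": 0.02, "b": 0.2}
        )
        # b outranks a despite being shorter; a no longer fits the budget
        assert design.marker_ids == ["b"]

    def test_exon_modes_agree_without_introns(self):
        rng = np.random.default_rng(0)
        candidates = [
            make_candidate(f"m{i}", [int(rng.integers(120, 2000))])
            for i in range(30)
        ]
        sel_a, _ = select_markers(candidates, RunConfig(max_baits=200))
        sel_b, _ = select_markers(
            candidates, RunConfig(max_baits=200, rank_mode="exon_plus_intron")
        )
        assert [r.marker_id for r in sel_a] == [r.marker_id for r in sel_b]

    def test_intron_aware_mode_prefers_more_shorter_markers(self):
        # an intron-rich pool: taking predicted intron length into account
        # selects at least as many markers, with shorter coding regions
        rng = np.random.default_rng(1)
        candidates = []
        for i in range(15):  # long-exon, intron-poor markers
            candidates.append(make_candidate(f"long{i:02d}", [int(rng.integers(2000, 3000))]))
        for i in range(25):  # shorter markers carrying many introns
            n_ex = int(rng.integers(4, 7))
            exons = [int(rng.integers(150, 400)) for _ in range(n_ex)]
            introns = [int(rng.integers(200, 800)) for _ in range(n_ex - 1)]
            candidates.append(make_candidate(f"rich{i:02d}", exons, introns))
        budget = RunConfig(max_baits=500)
        sel_exon, _ = select_markers(candidates, budget)
        budget_i = RunConfig(max_baits=500, rank_mode="exon_plus_intron")
        sel_intron, _ = select_markers(candidates, budget_i)
        assert len(sel_intron) >= len(sel_exon)
        mean_exon = lambda sel: np.mean([r.candidate.exon_len_total for r in sel])
        assert mean_exon(sel_intron) < mean_exon(sel_exon)

    @settings(max_examples=60, deadline=None)
    @given(
        st.lists(
            st.lists(st.integers(min_value=50, max_value=3000), min_size=1, max_size=5),
            min_size=1, max_size=20,
        ),
        st.integers(min_value=0, max_value=300),
    )
    def test_budget_is_never_exceeded(self, exon_sets, max_baits):
        cfg = RunConfig(max_baits=max_baits)
        candidates = [
            make_candidate(f"m{i:03d}", exons) for i, exons in enumerate(exon_sets)
        ]
        try:
            selected, design = select_markers(candidates, cfg)
        except ValueError:
            return
        assert design.n_baits <= max_baits
        assert design.footprint == sum(r.targetable_exon_len for r in selected)
        assert design.total_bait_len == design.n_baits * cfg.bait_len

    def test_greedy_is_near_optimal_against_knapsack_oracle(self):
        rng = np.random.default_rng(2)
        good = 0
        n_instances = 200
        for _ in range(n_instances):
            n = int(rng.integers(3, 11))
            candidates = [
                make_candidate(f"m{i:02d}", [int(rng.integers(120, 2500))])
                for i in range(n)
            ]
            budget = int(rng.integers(5, 60))
            cfg = RunConfig(max_baits=budget)
            selected, design = select_markers(candidates, cfg)
            assert design.n_baits <= budget
            ranked = rank_candidates(candidates, cfg)
            items = [(r.n_baits_needed, r.targetable_exon_len) for r in ranked]
            opt = knapsack_optimum(items, budget)
            greedy_value = sum(r.targetable_exon_len for r in selected)
            assert greedy_value <= opt
            if opt == 0 or greedy_value >= 0.9 * opt:
                good += 1
        assert good >= 0.9 * n_instances


class TestDesignReport:
    def test_published_budget_arithmetic(self):
        # one exon tiled into exactly 5,770 baits of 120 bp
        exon_len = 120 + 30 * 5769
        n, offsets = tile_baits(exon_len, 120, 4)
        assert n == 5770
        design = BaitDesign(
            marker_ids=["m"],
            baits=[("m", 0, o, o + 120) for o in offsets],
            bait_len=120, coverage=4, footprint=exon_len,
        )
        assert design.total_bait_len == 692_400
        assert design.nominal_footprint == 173_100
        report = design_report(design)
        assert report.attrs["total_bait_len"] == 692_400
        assert report.attrs["capture_footprint"] == 173_100

    def test_empty_design_reports_zero_totals(self):
        design = BaitDesign(marker_ids=[], baits=[], bait_len=120, coverage=4, footprint=0)
        report = design_report(design)
        total = report.iloc[-1]
        assert total["marker_id"] == "TOTAL"
        assert total["n_baits"] == 0
        assert report.attrs["total_bait_len"] == 0
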