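import itertools
import random

import numpy as np
import pytest

from baitkit.homology_engine import local_align
from baitkit.marker_discovery import (
    COPY_MULTI,
    COPY_SINGLE,
    call_copy_number,
    cluster_homologues,
    discover_markers,
    infer_gene_model,
    prefilter_by_length,
)
from baitkit.sequence_io import RunConfig, SequenceRecord, revcomp
from baitkit.synthetic_data import (
    SimParams,
    build_catalogue,
    simulate_genome_and_transcriptomes,
)

from conftest import random_seq, substituted


def _rec(rng, sid, source, n=1200):
    return SequenceRecord(id=sid, source=source, seq=random_seq(rng, n))


class TestPrefilter:
    def test_boundary_is_strictly_shorter(self):
        rng = np.random.default_rng(0)
        records = [
            SequenceRecord(id=f"r{n}", source="s", seq=random_seq(rng, n))
            for n in (999, 1000, 1001)
        ]
        kept = prefilter_by_length(records, 1000)
        assert [len(r) for r in kept] == [1000, 1001]

    def test_min_len_zero_is_identity_and_empty_passes_through(self):
        rng = np.random.default_rng(1)
        records = [_rec(rng, "a", "s", 10)]
        assert prefilter_by_length(records, 0) == records
        assert prefilter_by_length([], 1000) == []


class TestClusterHomologues:
    def test_shared_gene_forms_one_cluster(self):
        rng = np.random.default_rng(2)
        gene = random_seq(rng, 1200)
        tx1 = [SequenceRecord(id="g_t1", source="t1", seq=gene)]
        tx2 = [SequenceRecord(id="g_t2", source="t2", seq=substituted(rng, gene, 120))]
        clusters = cluster_homologues([tx1, tx2], 0.75, 100, 2)
        assert len(clusters) == 1
        assert clusters[0].members == [("t1", "g_t1"), ("t2", "g_t2")]
        assert clusters[0].min_pairwise_identity == pytest.approx(0.90, abs=0.01)

    def test_private_gene_forms_no_cluster(self):
        rng = np.random.default_rng(3)
        tx1 = [_rec(rng, "private", "t1")]
        tx2 = [_rec(rng, "other", "t2")]
        assert cluster_homologues([tx1, tx2], 0.75, 100, 2) == []

    def test_single_source_is_an_error(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError):
            cluster_homologues([[_rec(rng, "a", "t1")]], 0.75, 100, 2)

    def test_matches_brute_force_exact_clustering(self):
        # 5-gene single-copy core shared by both sources plus 2 private
        # genes each; the seeded clustering must equal connected components
        # of all-vs-all exhaustive local alignment
        rng = np.random.default_rng(5)
        core = [random_seq(rng, 700) for _ in range(5)]
        tx1 = [
            SequenceRecord(id=f"g{i}_t1", source="t1", seq=substituted(rng, g, 50))
            for i, g in enumerate(core)
        ] + [_rec(rng, f"p{i}_t1", "t1", 700) for i in range(2)]
        tx2 = [
            SequenceRecord(id=f"g{i}_t2", source="t2", seq=substituted(rng, g, 50))
            for i, g in enumerate(core)
        ] + [_rec(rng, f"p{i}_t2", "t2", 700) for i in range(2)]
        clusters = cluster_homologues([tx1, tx2], 0.75, 100, 2)
        assert len(clusters) == 5

        # brute-force oracle on the exact DP
        edges = set()
        for a, b in itertools.product(tx1, tx2):
            h = local_align(a.seq, b.seq)
            hr = local_align(a.seq, revcomp(b.seq))
            best = max((x for x in (h, hr) if x), key=lambda x: x.score, default=None)
            if (
                best
                and best.q_span >= 100
                and best.identity >= 0.75
                and best.score >= 100
            ):
                edges.add((a.id, b.id))
        oracle_pairs = {
            frozenset({m[1] for m in c.members}) for c in clusters
        }
        assert oracle_pairs == {frozenset(e) for e in edges}


class TestCallCopyNumber:
    def _cluster(self, rng, gene, n_tx=2):
        tx = []
        for t in range(n_tx):
            tx.append(
                SequenceRecord(
                    id=f"g_t{t}", source=f"t{t}", seq=substituted(rng, gene, 60)
                )
            )
        return cluster_homologues([[r] for r in tx], 0.75, 100, 2)[0]

    def test_single_locus_is_single(self, cfg):
        rng = np.random.default_rng(6)
        gene = random_seq(rng, 1200)
        cluster = self._cluster(rng, gene)
        genome = [
            SequenceRecord(
                id="scaf", source="genome",
                seq=random_seq(rng, 500) + gene + random_seq(rng, 500),
                role="genomic",
            )
        ]
        assert call_copy_number(cluster, genome, None, cfg) == COPY_SINGLE

    def test_planted_duplicate_locus_is_multi(self, cfg):
        rng = np.random.default_rng(7)
        gene = random_seq(rng, 1200)
        cluster = self._cluster(rng, gene)
        dup = substituted(rng, gene, 180)  # 85% identity paralog
        genome = [
            SequenceRecord(id="scaf1", source="genome",
                           seq=random_seq(rng, 400) + gene + random_seq(rng, 400),
                           role="genomic"),
            SequenceRecord(id="scaf2", source="genome",
                           seq=random_seq(rng, 400) + dup + random_seq(rng, 400),
                           role="genomic"),
        ]
        assert call_copy_number(cluster, genome, None, cfg) == COPY_MULTI

    def test_intra_source_duplicates_force_multi(self, cfg):
        rng = np.random.default_rng(8)
        gene = random_seq(rng, 1200)
        copy_b = substituted(rng, gene, 120)
        tx1 = [
            SequenceRecord(id="ga_t1", source="t1", seq=gene),
            SequenceRecord(id="gb_t1", source="t1", seq=copy_b),
        ]
        tx2 = [SequenceRecord(id="ga_t2", source="t2", seq=substituted(rng, gene, 60))]
        (cluster,) = cluster_homologues([tx1, tx2], 0.75, 100, 2)
        genome = [
            SequenceRecord(id="scaf", source="genome",
                           seq=random_seq(rng, 400) + gene + random_seq(rng, 400),
                           role="genomic")
        ]
        assert call_copy_number(cluster, genome, None, cfg) == COPY_MULTI

    def test_neither_genome_nor_catalogue_is_an_error(self, cfg):
        rng = np.random.default_rng(9)
        cluster = self._cluster(rng, random_seq(rng, 1200))
        with pytest.raises(ValueError):
            call_copy_number(cluster, None, None, cfg)

    def test_catalogue_flags_drive_the_call(self, cfg):
        rng = np.random.default_rng(10)
        gene = random_seq(rng, 1200)
        cluster = self._cluster(rng, gene)
        single_cat = [
            SequenceRecord(id="cat1", source="cat", seq=substituted(rng, gene, 120),
                           description="single")
        ]
        multi_cat = [
            SequenceRecord(id="cat1", source="cat", seq=substituted(rng, gene, 120),
                           description="multi")
        ]
        assert call_copy_number(cluster, None, single_cat, cfg) == COPY_SINGLE
        assert call_copy_number(cluster, None, multi_cat, cfg) == COPY_MULTI


class TestInferGeneModel:
    def test_contiguous_transcript_is_one_exon(self, cfg):
        rng = np.random.default_rng(11)
        tx = random_seq(rng, 1100)
        genome = [
            SequenceRecord(id="scaf", source="genome",
                           seq=random_seq(rng, 600) + tx + random_seq(rng, 600),
                           role="genomic")
        ]
        model = infer_gene_model(
            SequenceRecord(id="t", source="t1", seq=tx), genome, cfg
        )
        assert model is not None
        assert model.exons == [(600, 1700)]
        assert model.introns == []
        assert model.strand == "+"
        assert model.exon_len_total == 1100

    def _planted(self, rng, exon_lens, intron_lens):
        exons = [random_seq(rng, n) for n in exon_lens]
        introns = []
        for i, n in enumerate(intron_lens):
            intron = random_seq(rng, n)
            while intron[0] == exons[i + 1][0]:
                intron = random_seq(rng, 1) + intron[1:]
            while intron[-1] == exons[i][-1]:
                intron = intron[:-1] + random_seq(rng, 1)
            introns.append(intron)
        gseq = exons[0]
        for intron, exon in zip(introns, exons[1:]):
            gseq += intron + exon
        return "".join(exons), gseq

    def test_three_exon_structure_recovered_exactly(self, cfg):
        rng = np.random.default_rng(12)
        tx, gene = self._planted(rng, [400, 150, 500], [250, 800])
        genome = [
            SequenceRecord(id="scaf", source="genome",
                           seq=random_seq(rng, 500) + gene + random_seq(rng, 500),
                           role="genomic")
        ]
        model = infer_gene_model(
            SequenceRecord(id="t", source="t1", seq=tx), genome, cfg
        )
        assert model.exons == [(500, 900), (1150, 1300), (2100, 2600)]
        assert model.intron_lens == [250, 800]
        assert model.exon_len_total == 1050

    def test_minus_strand_locus_recovered(self, cfg):
        rng = np.random.default_rng(13)
        tx, gene = self._planted(rng, [500, 600], [300])
        genome = [
            SequenceRecord(id="scaf", source="genome",
                           seq=random_seq(rng, 500) + revcomp(gene) + random_seq(rng, 500),
                           role="genomic")
        ]
        model = infer_gene_model(
            SequenceRecord(id="t", source="t1", seq=tx), genome, cfg
        )
        assert model.strand == "-"
        # exon of 600 bp is upstream on the forward strand
        assert model.exons == [(500, 1100), (1400, 1900)]
        assert model.intron_lens == [300]
        # transcript intervals run antiparallel to the genome
        assert model.t_intervals == [(500, 1100), (0, 500)]

    def test_sub_minimum_intron_absorbed(self, cfg):
        rng = np.random.default_rng(14)
        tx, gene = self._planted(rng, [600, 500], [10])
        genome = [
            SequenceRecord(id="scaf", source="genome",
                           seq=random_seq(rng, 500) + gene + random_seq(rng, 500),
                           role="genomic")
        ]
        model = infer_gene_model(
            SequenceRecord(id="t", source="t1", seq=tx), genome, cfg
        )
        assert len(model.exons) == 1
        assert model.introns == []
        assert model.exons == [(500, 500 + 600 + 10 + 500)]

    def test_unalignable_insert_rejects_model(self, cfg):
        rng = np.random.default_rng(15)
        left, right = random_seq(rng, 600), random_seq(rng, 600)
        tx = left + random_seq(rng, 80) + right  # 80 bp absent from the locus
        genome = [
            SequenceRecord(id="scaf", source="genome",
                           seq=random_seq(rng, 400) + left + right + random_seq(rng, 400),
                           role="genomic")
        ]
        model = infer_gene_model(
            SequenceRecord(id="t", source="t1", seq=tx), genome, cfg
        )
        assert model is None


class TestDiscoverMarkers:
    def test_planted_composition_recovered(self, cfg):
        # 12 single-copy shared genes, 3 paralog families, 4 private genes,
        # 2 shared homologue pairs near 60% identity -> exactly the 12
        params = SimParams(
            n_genes=21, paralog_fraction=3 / 21, private_gene_fraction=4 / 21,
            diverged_fraction=2 / 21, seed=9,
        )
        genome, transcriptomes, truth = simulate_genome_and_transcriptomes(params)
        candidates = discover_markers(transcriptomes, genome, None, cfg)
        families = {
            truth.family_of_transcript(c.cluster.representative[1])
            for c in candidates
        }
        expected = truth.expected_marker_families(cfg)
        assert len(expected) == 12
        assert families == expected
        assert all(c.copy_number == COPY_SINGLE for c in candidates)
        assert all(
            c.identity_to_nearest_homologue >= cfg.min_identity for c in candidates
        )

    def test_identical_transcriptomes_with_single_catalogue(self, cfg):
        rng = np.random.default_rng(16)
        genes = [random_seq(rng, 1100) for _ in range(3)]
        tx1 = [SequenceRecord(id=f"g{i}_a", source="a", seq=g) for i, g in enumerate(genes)]
        tx2 = [SequenceRecord(id=f"g{i}_b", source="b", seq=g) for i, g in enumerate(genes)]
        catalogue = [
            SequenceRecord(id=f"cat{i}", source="cat", seq=g, description="single")
            for i, g in enumerate(genes)
        ]
        candidates = discover_markers([tx1, tx2], None, catalogue, cfg)
        assert len(candidates) == 3
        assert all(c.copy_number == COPY_SINGLE for c in candidates)
        assert all(c.model is None for c in candidates)

    def test_empty_intersection_yields_no_markers(self, cfg):
        rng = np.random.default_rng(17)
        tx1 = [_rec(rng, "a1", "a"), _rec(rng, "a2", "a")]
        tx2 = [_rec(rng, "b1", "b")]
        catalogue = [_rec(rng, "cat1", "cat")]
        assert discover_markers([tx1, tx2], None, catalogue, cfg) == []

    def test_permutation_invariance(self, cfg, small_fixture):
        _, genome, transcriptomes, _ = small_fixture
        base = discover_markers(transcriptomes, genome, None, cfg)
        shuffled = []
        rnd = random.Random(1)
        for recs in transcriptomes:
            recs = list(recs)
            rnd.shuffle(recs)
            shuffled.append(recs)
        alt = discover_markers(shuffled, genome, None, cfg)
        assert [c.marker_id for c in alt] == [c.marker_id for c in base]
        assert [c.cluster.members for c in alt] == [c.cluster.members for c in base]
        assert [c.copy_number for c in alt] == [c.copy_number for c in base]

    def test_raising_identity_floor_never_adds_markers(self, cfg, small_fixture):
        _, genome, transcriptomes, _ = small_fixture
        lax = discover_markers(transcriptomes, genome, None, cfg)
        strict_cfg = RunConfig(min_identity=0.9)
        strict = discover_markers(transcriptomes, genome, None, strict_cfg)
        assert len(strict) <= len(lax)
        assert {c.marker_id for c in strict} <= {c.marker_id for c in lax}


class TestFixtureInvariants:
    def test_emitted_candidates_satisfy_contracts(self, cfg, discovery_fixture):
        truth = discovery_fixture["truth"]
        for c in discovery_fixture["candidates"]:
            assert c.copy_number == COPY_SINGLE
            assert c.identity_to_nearest_homologue >= cfg.min_identity
            assert c.cluster.min_pairwise_identity >= cfg.min_identity
            fam = truth.family_of_transcript(c.cluster.representative[1])
            gene = next(g for g in truth.genes if g.family_id == fam)
            assert gene.copy_number == "single"

    def test_exon_reconstruction_tiles_the_transcript(self, discovery_fixture):
        for c in discovery_fixture["candidates"]:
            m = c.model
            assert m is not None
            # exons non-overlapping, sorted; introns exactly the gaps
            for (s0, e0), (s1, e1) in zip(m.exons, m.exons[1:]):
                assert e0 <= s1
            assert m.introns == [
                (m.exons[i][1], m.exons[i + 1][0]) for i in range(len(m.exons) - 1)
            ]
            covered = sorted(m.t_intervals)
            assert covered[0][0] == 0
            assert covered[-1][1] == len(c.seq)
            for (s0, e0), (s1, e1) in zip(covered, covered[1:]):
                assert e0 == s1
            assert sum(e - s for s, e in m.t_intervals) == len(c.seq)
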