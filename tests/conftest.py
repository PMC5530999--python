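import numpy as np
import pytest

from baitkit.marker_discovery import discover_markers
from baitkit.sequence_io import RunConfig, SequenceRecord
from baitkit.synthetic_data import SimParams, simulate_genome_and_transcriptomes


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def substituted(rng: np.random.Generator, seq: str, n_sub: int) -> str:
    """Copy of ``seq`` with exactly ``n_sub`` positions substituted."""
    out = list(seq)
    for p in rng.choice(len(seq), n_sub, replace=False):
        old = "ACGT".index(out[p])
        out[p] = "ACGT"[(old + 1 + rng.integers(0, 3)) % 4]
    return "".join(out)


@pytest.fixture(scope="session")
def cfg() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def discovery_fixture(cfg):
    """Default 20-gene / 3-taxon simulated study (genome + transcriptomes +
    truth) with the discovery pipeline already run on it."""
    params = SimParams(seed=0)
    genome, transcriptomes, truth = simulate_genome_and_transcriptomes(params)
    candidates = discover_markers(transcriptomes, genome, None, cfg)
    return {
        "params": params,
        "genome": genome,
        "transcriptomes": transcriptomes,
        "truth": truth,
        "candidates": candidates,
    }


@pytest.fixture(scope="module")
def small_fixture():
    """A cheap 6-gene / 2-taxon study used by tests that re-run discovery."""
    params = SimParams(
        n_genes=6, n_taxa=2, paralog_fraction=1 / 6, private_gene_fraction=1 / 6,
        diverged_fraction=1 / 6, n_scaffolds=2, exon_count_range=(2, 3), seed=4,
    )
    genome, transcriptomes, truth = simulate_genome_and_transcriptomes(params)
    return params, genome, transcriptomes, truth


def make_target(rng: np.random.Generator, tid: str, n: int) -> SequenceRecord:
    return SequenceRecord(id=tid, source="targets", seq=random_seq(rng, n), role="target")
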