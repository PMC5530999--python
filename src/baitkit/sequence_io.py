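"""FASTA input/output, run configuration and sequence records.

All coordinates inside the toolkit are 0-based, half-open.  Reports written
for human consumption (GFF3, BLAST-style TSV) convert to 1-based inclusive.
Sequences are upper-cased at load time and must be drawn from the IUPAC
nucleotide alphabet; anything else is rejected because downstream identity
computations are undefined for it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml
from Bio import SeqIO
from Bio.Seq import Seq, reverse_complement as _bio_revcomp
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

#: Upper-case IUPAC nucleotide letters (unambiguous + ambiguity codes).
IUPAC_LETTERS = frozenset("ACGTUNRYSWKMBDHV")

ROLES = ("transcript", "genomic", "contig", "target")


class FastaParseError(ValueError):
    """Raised for structurally malformed FASTA input."""


class ConfigError(ValueError):
    """Raised when a run-configuration value violates an invariant."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence tagged with its source dataset.

    Parameters
    ----------
    id:
        Identifier, unique within ``source``.
    source:
        Dataset label (transcriptome id, genome id or sample id).
    seq:
        Upper-case nucleotide string over the IUPAC alphabet.
    role:
        One of ``transcript``, ``genomic``, ``contig``, ``target``.
    description:
        Free-text remainder of the FASTA header (used e.g. for copy-number
        flags in single-copy catalogues).
    """

    id: str
    source: str
    seq: str
    role: str = "transcript"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SequenceRecord.id must be non-empty")
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r} for {self.id!r}")
        seq = self.seq.upper().replace("U", "T")
        bad = set(seq) - IUPAC_LETTERS
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-IUPAC characters: "
                f"{sorted(bad)}"
            )
        object.__setattr__(self, "seq", seq)

    def __len__(self) -> int:
        return len(self.seq)


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware (R<->Y, etc.)."""
    return str(_bio_revcomp(Seq(seq)))


@dataclass
class RunConfig:
    """All tunable thresholds of the pipeline.

    Defaults reproduce the published parameterisation: a budget of 5,770
    baits of 120 bp tiled at 4x (total bait length 692,400 bp), homologues
    shared by at least two transcriptomes, a >=75% identity floor (probe
    hybridisation tolerates at most 25% divergence), exons below 120 bp
    excluded as bait targets, contigs kept when they overlap a target by
    >=100 bp, and contig merging requiring >=30 bp of overlap.
    """

    # stage 1: discovery
    min_transcript_len: int = 1000
    min_shared_transcriptomes: int = 2
    min_identity: float = 0.75
    # stage 2: selection / bait design
    bait_len: int = 120
    tiling_coverage: int = 4
    max_baits: int = 5770
    min_exon_len: int = 120
    rank_mode: str = "exon_length"
    # post-processing of captured contigs
    min_target_overlap: int = 100
    min_merge_overlap: int = 30
    # search engine knobs
    seed_len: int = 11
    band: int = 15
    min_hit_len: int = 100
    cluster_min_identity: float = 0.55
    cluster_min_score: int = 100
    catalogue_min_identity: float = 0.70
    mapping_min_hit_len: int = 40
    # gene-model / copy-number structure
    locus_merge_gap: int = 10_000
    min_intron_len: int = 20
    transcript_gap_tol: int = 30
    min_locus_coverage: float = 0.5
    paralog_split_identity: float = 0.90
    mean_intron_scope: str = "global"
    seed: int = 0

    RANK_MODES = (
        "exon_length",
        "exon_plus_intron",
        "variability",
        "length_times_variability",
    )

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (0.0 < self.min_identity <= 1.0):
            raise ConfigError("min_identity must satisfy 0 < x <= 1")
        if not (0.0 < self.cluster_min_identity <= 1.0):
            raise ConfigError("cluster_min_identity must satisfy 0 < x <= 1")
        if self.bait_len <= 0:
            raise ConfigError("bait_len must be positive")
        if self.tiling_coverage < 1:
            raise ConfigError("tiling_coverage must be >= 1")
        if self.bait_len % self.tiling_coverage != 0:
            raise ConfigError(
                "bait_len must be divisible by tiling_coverage "
                f"({self.bait_len} / {self.tiling_coverage} is not integral)"
            )
        if self.max_baits < 0:
            raise ConfigError("max_baits must be >= 0")
        if self.min_shared_transcriptomes < 2:
            raise ConfigError("min_shared_transcriptomes must be >= 2")
        if self.rank_mode not in self.RANK_MODES:
            raise ConfigError(f"rank_mode must be one of {self.RANK_MODES}")
        if self.mean_intron_scope not in ("global", "per_marker"):
            raise ConfigError("mean_intron_scope must be global or per_marker")
        for key in (
            "min_transcript_len",
            "min_exon_len",
            "min_target_overlap",
            "min_merge_overlap",
            "seed_len",
            "min_hit_len",
            "locus_merge_gap",
            "min_intron_len",
            "transcript_gap_tol",
        ):
            if getattr(self, key) < 0:
                raise ConfigError(f"{key} must be >= 0")

    @property
    def tiling_step(self) -> int:
        return self.bait_len // self.tiling_coverage


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML run configuration, applying defaults for absent keys."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config {path} is not a key/value mapping")
        data = loaded
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    try:
        return RunConfig(**data)
    except TypeError as exc:  # wrong value type
        raise ConfigError(str(exc)) from exc


def read_fasta(path: str | Path, source: str, role: str = "transcript") -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Order is preserved, sequences are upper-cased, and duplicated ids within
    one file raise :class:`FastaParseError`.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: text before first FASTA header"
                )
            break
        else:
            raise FastaParseError(f"{path}: no FASTA entries found")

    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if not entry.seq:
            raise FastaParseError(f"{path}: entry {entry.id!r} has an empty sequence")
        if entry.id in seen:
            raise FastaParseError(f"{path}: duplicated id {entry.id!r}")
        seen.add(entry.id)
        desc = entry.description[len(entry.id):].strip()
        try:
            records.append(
                SequenceRecord(
                    id=entry.id, source=source, seq=str(entry.seq),
                    role=role, description=desc,
                )
            )
        except ValueError as exc:
            raise FastaParseError(f"{path}: {exc}") from exc
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA (60-column wrapping, header = id)."""
    if not records:
        raise ValueError("write_fasta: record list is empty")
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(bio, fh, "fasta")


def check_unique(records: Iterable[SequenceRecord]) -> None:
    """Enforce global (source, id) uniqueness after loading several files."""
    seen: set[tuple[str, str]] = set()
    for r in records:
        key = (r.source, r.id)
        if key in seen:
            raise ValueError(f"duplicate record {key} across inputs")
        seen.add(key)


def write_tsv(df, path: str | Path, comment: str) -> None:
    """Write a tabular report as TSV with a commented header line."""
    with open(path, "w") as fh:
        fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False)
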