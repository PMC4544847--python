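"""Read-filtering cascade for shotgun metagenomes.

Four stages, applied in order: (1) host-read removal by a canonical k-mer
screen against a host reference, (2) exact-sequence duplicate removal,
(3) trimming of ambiguous (N) runs from read ends, (4) a quality/length
filter over the leading bases of each read. A library whose surviving read
count falls below ``min_reads_after_filtering`` is flagged CNBP ("could not
be performed") and excluded from similarity analysis downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kmers import kmer_set, shared_count
from .synthetic_data import ReadRecord, SampleLibrary


@dataclass
class QCConfig:
    """Thresholds for the filtering cascade.

    ``prefix_length``/``min_length`` default to 80 bases (HiSeq-style 93 bp
    reads); use 120 for MiSeq-style 150 bp reads. ``min_quality`` is the
    minimum mean Phred score over the prefix. ``min_reads_after_filtering``
    defaults to the 10-million-read depth gate appropriate for real
    sequencing runs; desk-scale synthetic cohorts lower it explicitly.
    """

    prefix_length: int = 80
    min_quality: float = 6.0
    min_length: int = 80
    min_reads_after_filtering: int = 10_000_000
    host_kmer_length: int = 31
    host_min_shared_kmers: int = 2

    def __post_init__(self) -> None:
        if min(self.prefix_length, self.min_length, self.host_kmer_length) < 1:
            raise ValueError("length thresholds must be positive")
        if self.min_quality < 0 or self.host_min_shared_kmers < 1:
            raise ValueError("invalid quality or k-mer thresholds")


@dataclass
class QCReport:
    """Per-stage removal counts; input == removals + remaining always holds."""

    sample_id: str
    n_input: int
    host_removed: int = 0
    duplicates_removed: int = 0
    low_quality_removed: int = 0
    short_removed: int = 0
    reads_remaining: int = 0
    cnbp_flag: bool = False
    stage_fractions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        removed = (
            self.host_removed
            + self.duplicates_removed
            + self.low_quality_removed
            + self.short_removed
        )
        if removed + self.reads_remaining != self.n_input:
            raise ValueError(
                f"QC counts do not reconcile for {self.sample_id}: "
                f"{removed} removed + {self.reads_remaining} remaining != {self.n_input}"
            )

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "n_input": self.n_input,
            "host_removed": self.host_removed,
            "duplicates_removed": self.duplicates_removed,
            "low_quality_removed": self.low_quality_removed,
            "short_removed": self.short_removed,
            "reads_remaining": self.reads_remaining,
            "cnbp_flag": self.cnbp_flag,
        }


def build_host_index(host_sequences, k: int) -> set[str]:
    """Canonical k-mer set over one or more host reference sequences."""
    if isinstance(host_sequences, str):
        host_sequences = [host_sequences]
    index: set[str] = set()
    for seq in host_sequences:
        index |= kmer_set(seq, k)
    if not index:
        raise ValueError("host reference yielded no k-mers (empty or too short)")
    return index


def _clone(library: SampleLibrary, reads: list[ReadRecord]) -> SampleLibrary:
    return SampleLibrary(
        sample_id=library.sample_id,
        subject_id=library.subject_id,
        role=library.role,
        timepoint_label=library.timepoint_label,
        reads=reads,
        paired_flag=library.paired_flag,
    )


def remove_host_reads(
    library: SampleLibrary,
    host_index: set[str],
    config: QCConfig | None = None,
) -> tuple[SampleLibrary, int]:
    """Drop reads sharing >= ``host_min_shared_kmers`` canonical k-mers with the host.

    ``host_index`` is the set from :func:`build_host_index`. Order of the
    surviving reads is preserved.
    """
    config = config or QCConfig()
    kept = [
        r
        for r in library.reads
        if shared_count(
            r.sequence,
            host_index,
            config.host_kmer_length,
            stop_at=config.host_min_shared_kmers,
        )
        < config.host_min_shared_kmers
    ]
    return _clone(library, kept), library.n_reads - len(kept)


def remove_duplicates(library: SampleLibrary) -> tuple[SampleLibrary, int]:
    """Keep only the first occurrence of each exact read sequence.

    Duplicates are assessed on the raw (untrimmed) sequence, mates treated
    independently.
    """
    seen: set[str] = set()
    kept = []
    for r in library.reads:
        if r.sequence not in seen:
            seen.add(r.sequence)
            kept.append(r)
    return _clone(library, kept), library.n_reads - len(kept)


def trim_ambiguous_ends(read: ReadRecord) -> ReadRecord:
    """Strip leading/trailing runs of N (sequence and quality in lockstep).

    Interior Ns are untouched; a read that trims to nothing is returned
    empty and left for the length filter.
    """
    seq = read.sequence
    start = 0
    end = len(seq)
    while start < end and seq[start] == "N":
        start += 1
    while end > start and seq[end - 1] == "N":
        end -= 1
    if start == 0 and end == len(seq):
        return read
    return ReadRecord(read.read_id, seq[start:end], read.quality[start:end], read.mate)


def _mean_prefix_quality(read: ReadRecord, prefix_length: int) -> float:
    q = read.phred[:prefix_length]
    return float(np.mean(q)) if q.size else 0.0


def quality_filter(
    library: SampleLibrary, config: QCConfig | None = None
) -> tuple[SampleLibrary, int, int]:
    """Remove short reads and reads with poor leading-base quality.

    A read is dropped when its post-trimming length is below ``min_length``,
    or its mean Phred score over the first ``prefix_length`` bases is below
    ``min_quality``. Returns (library, n_low_quality, n_short).
    """
    config = config or QCConfig()
    kept = []
    n_lowq = n_short = 0
    for r in library.reads:
        if len(r) < config.min_length:
            n_short += 1
        elif _mean_prefix_quality(r, config.prefix_length) < config.min_quality:
            n_lowq += 1
        else:
            kept.append(r)
    return _clone(library, kept), n_lowq, n_short


def apply_qc(
    library: SampleLibrary,
    host_reference,
    config: QCConfig | None = None,
) -> tuple[SampleLibrary, QCReport]:
    """Run the full cascade: host -> duplicates -> end-trim -> quality/length.

    ``host_reference`` may be a sequence, a list of sequences, or a
    prebuilt k-mer set. Host removal precedes deduplication, so a host read
    never counts as a duplicate. The CNBP flag is set purely from
    ``reads_remaining`` versus ``min_reads_after_filtering``.
    """
    config = config or QCConfig()
    n_input = library.n_reads
    host_index = (
        host_reference
        if isinstance(host_reference, set)
        else build_host_index(host_reference, config.host_kmer_length)
    )
    library, n_host = remove_host_reads(library, host_index, config)
    library, n_dup = remove_duplicates(library)
    library = _clone(library, [trim_ambiguous_ends(r) for r in library.reads])
    library, n_lowq, n_short = quality_filter(library, config)

    report = QCReport(
        sample_id=library.sample_id,
        n_input=n_input,
        host_removed=n_host,
        duplicates_removed=n_dup,
        low_quality_removed=n_lowq,
        short_removed=n_short,
        reads_remaining=library.n_reads,
        cnbp_flag=library.n_reads < config.min_reads_after_filtering,
    )
    if n_input:
        report.stage_fractions = {
            "host": n_host / n_input,
            "duplicate": n_dup / n_input,
            "low_quality": n_lowq / n_input,
            "short": n_short / n_input,
        }
    return library, report
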