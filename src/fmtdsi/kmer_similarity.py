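"""Alignment-free sample-to-sample similarity via shared k-mers.

The shared-read criterion: a read of sample A is "shared" with sample B if
it contains at least ``t`` distinct (canonical) k-mers that occur anywhere
in B's reads. The similarity of A to B is the percentage of A's reads
shared with B. Defaults are t=2 shared k-mers of length k=30.

The membership structure is an exact set rather than a Bloom filter:
desk-scale libraries fit comfortably in memory, and exactness makes the
kernel verifiable against a brute-force oracle with no false-positive rate
to reason about.

Boundary note: a read of length exactly k contributes a single k-mer and
can therefore never reach t=2; such reads are counted in the denominator
but can never be shared. This is a property of the criterion, not an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from ._kmers import kmer_set, shared_count
from .synthetic_data import ReadRecord, SampleLibrary


@dataclass
class SimilarityConfig:
    k: int = 30
    t: int = 2
    canonical: bool = True

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.t < 1:
            raise ValueError("t must be >= 1")


@dataclass
class KmerIndex:
    """Set of distinct (canonical) k-mers observed across a library's reads."""

    sample_id: str
    k: int
    kmers: set[str] = field(default_factory=set)
    canonical: bool = True

    @property
    def n_kmers(self) -> int:
        return len(self.kmers)

    def __contains__(self, kmer: str) -> bool:
        return kmer in self.kmers


@dataclass
class SimilarityResult:
    """Directional and symmetric shared-read percentages for a library pair."""

    query_id: str
    target_id: str
    n_query_reads: int
    n_target_reads: int
    n_query_shared: int
    n_target_shared: int

    @property
    def pct_query_in_target(self) -> float:
        return 100.0 * self.n_query_shared / self.n_query_reads

    @property
    def pct_target_in_query(self) -> float:
        return 100.0 * self.n_target_shared / self.n_target_reads

    @property
    def symmetric_pct(self) -> float:
        return (
            100.0
            * (self.n_query_shared + self.n_target_shared)
            / (self.n_query_reads + self.n_target_reads)
        )


def build_index(library: SampleLibrary, config: SimilarityConfig | None = None) -> KmerIndex:
    """Index every (canonical) k-mer of every read; k-mers containing N are skipped."""
    config = config or SimilarityConfig()
    kmers: set[str] = set()
    for read in library.reads:
        kmers |= kmer_set(read.sequence, config.k, canonical=config.canonical)
    return KmerIndex(
        sample_id=library.sample_id, k=config.k, kmers=kmers, canonical=config.canonical
    )


def shared_kmer_count(read: ReadRecord | str, index: KmerIndex) -> int:
    """Distinct (canonical) k-mers of the read present in the index."""
    seq = read if isinstance(read, str) else read.sequence
    return shared_count(seq, index.kmers, index.k, canonical=index.canonical)


def _n_shared_reads(library: SampleLibrary, index: KmerIndex, t: int) -> int:
    return sum(
        1
        for read in library.reads
        if shared_count(read.sequence, index.kmers, index.k, canonical=index.canonical, stop_at=t)
        >= t
    )


def similarity(
    query_library: SampleLibrary,
    target_library: SampleLibrary,
    config: SimilarityConfig | None = None,
    *,
    query_index: KmerIndex | None = None,
    target_index: KmerIndex | None = None,
) -> SimilarityResult:
    """Both directional shared-read percentages for a pair of libraries.

    Pass prebuilt indexes to amortize index construction across many pairs.
    Raises on empty libraries, where the percentage is undefined.
    """
    config = config or SimilarityConfig()
    if query_library.n_reads == 0 or target_library.n_reads == 0:
        raise ValueError("similarity undefined for empty libraries")
    target_index = target_index or build_index(target_library, config)
    query_index = query_index or build_index(query_library, config)
    return SimilarityResult(
        query_id=query_library.sample_id,
        target_id=target_library.sample_id,
        n_query_reads=query_library.n_reads,
        n_target_reads=target_library.n_reads,
        n_query_shared=_n_shared_reads(query_library, target_index, config.t),
        n_target_shared=_n_shared_reads(target_library, query_index, config.t),
    )


def save_index(index: KmerIndex, path) -> None:
    """Sorted-text index format: a header line, then one k-mer per line."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"#sample={index.sample_id}\tk={index.k}\tcanonical={int(index.canonical)}\n")
        for km in sorted(index.kmers):
            fh.write(km + "\n")


def load_index(path) -> KmerIndex:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().strip()
        if not header.startswith("#sample="):
            raise ValueError(f"not an index file: {path}")
        fields = dict(part.split("=", 1) for part in header[1:].split("\t"))
        kmers = {line.strip() for line in fh if line.strip()}
    return KmerIndex(
        sample_id=fields["sample"],
        k=int(fields["k"]),
        kmers=kmers,
        canonical=bool(int(fields.get("canonical", "1"))),
    )
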