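"""Synthetic donor/recipient metagenome cohorts with known engraftment ground truth.

The generator emulates the data a small FMT (fecal microbiota
transplantation) study produces: per-subject species abundance profiles,
shotgun read libraries drawn from synthetic genomes, host-read
contamination, base-call errors with matching quality strings, duplicate
reads, and post-transplant communities formed as donor/recipient mixtures
with a time-varying engraftment fraction pi. Because the mixing fraction is
known exactly, every downstream stage (QC, similarity, DSI, profiling) can
be tested against ground truth without any external sequencing data.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np

from ._kmers import kmer_set, reverse_complement

#: Study timepoint vocabulary: two pre-transplant baselines, transplant day,
#: and the 1-week / 1-month / 2-3-month follow-ups.
TIMEPOINTS = ("BL1", "BL2", "TP", "WK1", "MO1", "MO2_3")
POST_TIMEPOINTS = ("WK1", "MO1", "MO2_3")

_BASES = "ACGT"
_Q_GOOD = 38  # error-free base
_Q_ERR = 8  # substituted base
_Q_BAD = 2  # every base of an injected "bad" read

_ABUNDANCE_TOL = 1e-9


@dataclass
class ReadRecord:
    """A single sequencing read with Phred+33-encoded quality string."""

    read_id: str
    sequence: str
    quality: str
    mate: int | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(
                f"read {self.read_id}: sequence and quality lengths differ "
                f"({len(self.sequence)} vs {len(self.quality)})"
            )

    @property
    def phred(self) -> np.ndarray:
        """Per-base Phred scores as an integer array."""
        return np.frombuffer(self.quality.encode("ascii"), dtype=np.uint8).astype(int) - 33

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SampleLibrary:
    """An ordered read collection plus the sample's cohort metadata."""

    sample_id: str
    subject_id: str
    role: str  # "donor" | "recipient"
    timepoint_label: str
    reads: list[ReadRecord] = field(default_factory=list)
    paired_flag: bool = False

    def __post_init__(self) -> None:
        if self.role not in ("donor", "recipient"):
            raise ValueError(f"role must be donor or recipient, got {self.role!r}")
        if self.timepoint_label not in TIMEPOINTS:
            raise ValueError(
                f"unknown timepoint {self.timepoint_label!r}; expected one of {TIMEPOINTS}"
            )
        ids = [r.read_id for r in self.reads]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate read ids in library {self.sample_id}")

    @property
    def n_reads(self) -> int:
        return len(self.reads)


@dataclass
class CommunityModel:
    """Ground-truth community: species pools, genomes, and noise parameters.

    ``donor_abundance`` and ``recipient_abundance`` are percent vectors over
    ``species_ids`` (each summing to 100); species absent from a subject are
    exactly 0. ``engraftment_schedule`` maps post-transplant timepoint labels
    to the mixing fraction pi in [0, 1]: the post community at that timepoint
    is (1-pi)*recipient + pi*donor, so pi is the ground-truth analogue of
    engraftment that the Donor Similarity Index estimates.
    """

    species_ids: list[str]
    genomes: dict[str, str]
    donor_abundance: np.ndarray
    recipient_abundance: np.ndarray
    engraftment_schedule: dict[str, float]
    host_sequence: str
    host_fraction: float = 0.0
    error_rate: float = 0.0
    duplicate_fraction: float = 0.0
    bad_read_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.donor_abundance = np.asarray(self.donor_abundance, dtype=float)
        self.recipient_abundance = np.asarray(self.recipient_abundance, dtype=float)
        for name, vec in (
            ("donor_abundance", self.donor_abundance),
            ("recipient_abundance", self.recipient_abundance),
        ):
            if vec.shape != (len(self.species_ids),):
                raise ValueError(f"{name} length does not match species_ids")
            if np.any(vec < 0) or abs(vec.sum() - 100.0) > _ABUNDANCE_TOL:
                raise ValueError(f"{name} must be non-negative and sum to 100")
        for label, pi in self.engraftment_schedule.items():
            if not 0.0 <= pi <= 1.0:
                raise ValueError(f"engraftment fraction for {label} outside [0, 1]: {pi}")
        for name, p in (
            ("host_fraction", self.host_fraction),
            ("error_rate", self.error_rate),
            ("duplicate_fraction", self.duplicate_fraction),
            ("bad_read_fraction", self.bad_read_fraction),
        ):
            if not 0.0 <= p < 1.0:
                raise ValueError(f"{name} must lie in [0, 1): {p}")


def _sample_seed(master_seed: int, sample_id: str) -> np.random.SeedSequence:
    """Derive an independent per-sample random stream.

    Hashing (sample_id, master seed) means adding or reordering samples in a
    cohort never perturbs the reads of any other sample.
    """
    digest = hashlib.sha256(f"{master_seed}:{sample_id}".encode()).digest()
    return np.random.SeedSequence([master_seed, int.from_bytes(digest[:4], "big")])


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    idx = rng.integers(0, 4, size=length)
    return bytes(np.frombuffer(b"ACGT", dtype=np.uint8)[idx]).decode("ascii")


def make_community(
    n_species: int,
    overlap_fraction: float = 0.5,
    distribution_params: dict | None = None,
    seed: int = 0,
    *,
    genome_length: int = 20_000,
    host_length: int = 100_000,
    engraftment_schedule: dict[str, float] | None = None,
    host_fraction: float = 0.0,
    error_rate: float = 0.0,
    duplicate_fraction: float = 0.0,
    bad_read_fraction: float = 0.0,
    species_prefix: str = "sp",
) -> CommunityModel:
    """Draw a donor/recipient community pair with known overlap.

    ``overlap_fraction`` sets the fraction of the ``n_species`` pool shared
    between donor and recipient; the remaining species are split between the
    two subjects and are exactly 0 in the other. Abundances over each
    subject's support are log-normal (sigma via ``distribution_params``,
    default 1.0) renormalized to 100%, giving the long-tailed profiles
    typical of gut communities. Deterministic given ``seed``.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must lie in [0, 1]")
    sigma = float((distribution_params or {}).get("sigma", 1.0))

    rng = np.random.default_rng(seed)
    width = len(str(n_species))
    species_ids = [f"{species_prefix}{i + 1:0{width}d}" for i in range(n_species)]
    genomes = {sid: _random_sequence(rng, genome_length) for sid in species_ids}
    host_sequence = _random_sequence(rng, host_length)

    n_shared = int(round(overlap_fraction * n_species))
    n_unique = n_species - n_shared
    donor_only = list(range(n_shared, n_shared + n_unique // 2 + n_unique % 2))
    recipient_only = list(range(n_shared + len(donor_only), n_species))
    donor_support = list(range(n_shared)) + donor_only
    recipient_support = list(range(n_shared)) + recipient_only

    def _draw(support: list[int]) -> np.ndarray:
        vec = np.zeros(n_species)
        raw = rng.lognormal(mean=0.0, sigma=sigma, size=len(support))
        vec[support] = 100.0 * raw / raw.sum()
        return vec

    donor_abundance = _draw(donor_support)
    recipient_abundance = _draw(recipient_support)

    if engraftment_schedule is None:
        # moderate engraftment at 1 week that wanes over the following months
        engraftment_schedule = {"WK1": 0.5, "MO1": 0.35, "MO2_3": 0.15}

    return CommunityModel(
        species_ids=species_ids,
        genomes=genomes,
        donor_abundance=donor_abundance,
        recipient_abundance=recipient_abundance,
        engraftment_schedule=dict(engraftment_schedule),
        host_sequence=host_sequence,
        host_fraction=host_fraction,
        error_rate=error_rate,
        duplicate_fraction=duplicate_fraction,
        bad_read_fraction=bad_read_fraction,
        seed=seed,
    )


def mix_communities(model: CommunityModel, timepoint_label: str) -> np.ndarray:
    """Post-transplant abundance vector at a scheduled timepoint.

    Returns (1-pi)*recipient + pi*donor for the schedule's pi; the convex
    combination keeps the vector summing to 100.
    """
    if timepoint_label not in model.engraftment_schedule:
        raise KeyError(f"timepoint {timepoint_label!r} not in engraftment schedule")
    pi = model.engraftment_schedule[timepoint_label]
    return (1.0 - pi) * model.recipient_abundance + pi * model.donor_abundance


def generate_reads(
    model: CommunityModel,
    abundance_vector: np.ndarray,
    n_reads: int,
    read_length: int = 93,
    *,
    sample_id: str,
    subject_id: str = "",
    role: str = "recipient",
    timepoint_label: str = "BL2",
) -> tuple[SampleLibrary, dict]:
    """Simulate a shotgun library from an abundance vector.

    Fragment start positions are uniform over each genome; strand is chosen
    uniformly, with minus-strand reads reverse-complemented. A
    ``host_fraction`` of reads is drawn from the host reference instead of a
    microbial genome. Substitutions are applied at ``error_rate`` with the
    base quality dropped accordingly; ``bad_read_fraction`` of reads get a
    uniformly terrible quality string (exercising the quality filter);
    ``duplicate_fraction`` * n_reads extra verbatim copies are appended.

    Returns the library plus a ground-truth sidecar dict recording, per
    read, its true origin (host / species), which reads are injected
    duplicates or bad reads, and the removal counts a QC cascade at default
    thresholds should observe. Deterministic given ``model.seed`` and
    ``sample_id``.
    """
    abundance_vector = np.asarray(abundance_vector, dtype=float)
    if abs(abundance_vector.sum() - 100.0) > 1e-6:
        raise ValueError("abundance vector must sum to 100")
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    genome_length = len(next(iter(model.genomes.values())))
    if read_length > genome_length:
        raise ValueError("read_length exceeds genome length")

    rng = np.random.default_rng(_sample_seed(model.seed, sample_id))
    n_species = len(model.species_ids)
    probs = abundance_vector / 100.0

    is_host = rng.random(n_reads) < model.host_fraction
    species_idx = rng.choice(n_species, size=n_reads, p=probs)
    host_starts = rng.integers(0, len(model.host_sequence) - read_length + 1, size=n_reads)
    starts = rng.integers(0, genome_length - read_length + 1, size=n_reads)
    minus_strand = rng.random(n_reads) < 0.5
    is_bad = rng.random(n_reads) < model.bad_read_fraction
    err_mask = rng.random((n_reads, read_length)) < model.error_rate
    err_offsets = rng.integers(1, 4, size=(n_reads, read_length))

    base_to_idx = {b: i for i, b in enumerate(_BASES)}
    good_q = chr(_Q_GOOD + 33)
    err_q = chr(_Q_ERR + 33)
    bad_quality = chr(_Q_BAD + 33) * read_length

    reads: list[ReadRecord] = []
    origin: dict[str, str] = {}  # read_id -> "host" or species id
    host_ids: list[str] = []
    bad_ids: list[str] = []
    width = len(str(n_reads * 2))
    for i in range(n_reads):
        rid = f"{sample_id}:r{i:0{width}d}"
        if is_host[i]:
            src = model.host_sequence
            start = int(host_starts[i])
            origin[rid] = "host"
            host_ids.append(rid)
        else:
            sid = model.species_ids[int(species_idx[i])]
            src = model.genomes[sid]
            start = int(starts[i])
            origin[rid] = sid
        seq = src[start : start + read_length]
        if minus_strand[i]:
            seq = reverse_complement(seq)
        if err_mask[i].any():
            chars = list(seq)
            quals = [good_q] * read_length
            for j in np.nonzero(err_mask[i])[0]:
                chars[j] = _BASES[(base_to_idx[chars[j]] + int(err_offsets[i, j])) % 4]
                quals[j] = err_q
            seq = "".join(chars)
            quality = "".join(quals)
        else:
            quality = good_q * read_length
        if is_bad[i]:
            quality = bad_quality
            bad_ids.append(rid)
        reads.append(ReadRecord(rid, seq, quality))

    n_dup = int(round(model.duplicate_fraction * n_reads))
    dup_ids: list[str] = []
    if n_dup:
        dup_sources = rng.integers(0, n_reads, size=n_dup)
        for j, src_i in enumerate(dup_sources):
            rid = f"{sample_id}:r{n_reads + j:0{width}d}"
            src_read = reads[int(src_i)]
            reads.append(ReadRecord(rid, src_read.sequence, src_read.quality))
            origin[rid] = origin[src_read.read_id]
            dup_ids.append(rid)
            if origin[rid] == "host":
                host_ids.append(rid)
            if src_read.quality == bad_quality:
                bad_ids.append(rid)

    library = SampleLibrary(
        sample_id=sample_id,
        subject_id=subject_id,
        role=role,
        timepoint_label=timepoint_label,
        reads=reads,
    )
    truth = _expected_qc_truth(library, origin, host_ids, dup_ids, bad_ids)
    truth.update(
        sample_id=sample_id,
        n_reads_emitted=len(reads),
        origin_of_read=origin,
        injected_duplicate_ids=dup_ids,
    )
    return library, truth


def _expected_qc_truth(
    library: SampleLibrary,
    origin: dict[str, str],
    host_ids: list[str],
    dup_ids: list[str],
    bad_ids: list[str],
) -> dict:
    """Removal counts the default QC cascade should observe at error_rate=0.

    Mirrors the cascade order (host -> duplicates -> trim -> quality) purely
    from ground-truth labels: host reads leave first, then sequence
    duplicates among the survivors (first occurrence kept, accidental
    collisions included), then reads whose mean quality fails the filter.
    """
    host_set = set(host_ids)
    bad_set = set(bad_ids)
    seen: set[str] = set()
    n_host = n_dup = n_bad = 0
    remaining = 0
    for read in library.reads:
        if read.read_id in host_set:
            n_host += 1
            continue
        if read.sequence in seen:
            n_dup += 1
            continue
        seen.add(read.sequence)
        if read.read_id in bad_set:
            n_bad += 1
            continue
        remaining += 1
    return {
        "host_read_ids": host_ids,
        "bad_read_ids": bad_ids,
        "expected_qc": {
            "host_removed": n_host,
            "duplicates_removed": n_dup,
            "low_quality_removed": n_bad,
            "short_removed": 0,
            "reads_remaining": remaining,
        },
    }


@dataclass
class MarkerDatabase:
    """Species-specific marker sequences for read-level taxonomic assignment.

    Stands in for a clade-specific marker-gene catalogue: every canonical
    ``kmer_length``-mer of every marker occurs in exactly one species'
    genome, so a read matching a marker k-mer identifies its source species
    unambiguously.
    """

    markers: dict[str, list[str]]
    marker_length: int
    kmer_length: int

    @property
    def species(self) -> list[str]:
        return list(self.markers)

    def to_fasta(self, path) -> None:
        from . import _io

        records = [
            (f"{sid}|m{i + 1:02d}", seq)
            for sid, seqs in self.markers.items()
            for i, seq in enumerate(seqs)
        ]
        _io.write_fasta(records, path)

    @classmethod
    def from_fasta(cls, path, kmer_length: int) -> "MarkerDatabase":
        from . import _io

        markers: dict[str, list[str]] = {}
        lengths = set()
        for name, seq in _io.read_fasta(path):
            sid = name.split("|")[0]
            markers.setdefault(sid, []).append(seq)
            lengths.add(len(seq))
        if not markers:
            raise ValueError(f"no marker records in {path}")
        return cls(markers=markers, marker_length=min(lengths), kmer_length=kmer_length)


def build_marker_db(
    genomes: dict[str, str],
    markers_per_species: int = 5,
    marker_length: int = 200,
    kmer_length: int = 30,
    seed: int = 0,
    max_retries: int = 100,
) -> MarkerDatabase:
    """Select species-unique marker windows from a set of genomes.

    Candidate windows are rejection-sampled until none of their canonical
    k-mers occurs in more than one species' genome; for random genomes the
    first draw almost always passes, but the check guards engineered or
    overlapping genome sets.
    """
    if marker_length < kmer_length:
        raise ValueError("marker_length must be >= kmer_length")
    # count, per canonical k-mer, how many distinct species carry it
    kmer_species_count: dict[str, int] = {}
    for seq in genomes.values():
        for km in kmer_set(seq, kmer_length):
            kmer_species_count[km] = kmer_species_count.get(km, 0) + 1

    rng = np.random.default_rng(seed)
    markers: dict[str, list[str]] = {}
    for sid, genome in genomes.items():
        chosen: list[str] = []
        for _ in range(markers_per_species):
            for _attempt in range(max_retries):
                start = int(rng.integers(0, len(genome) - marker_length + 1))
                window = genome[start : start + marker_length]
                if all(kmer_species_count[km] == 1 for km in kmer_set(window, kmer_length)):
                    chosen.append(window)
                    break
            else:
                raise RuntimeError(
                    f"could not find a species-unique marker for {sid} "
                    f"after {max_retries} attempts"
                )
        markers[sid] = chosen
    return MarkerDatabase(markers=markers, marker_length=marker_length, kmer_length=kmer_length)


def make_marker_db(
    model: CommunityModel,
    markers_per_species: int = 5,
    marker_length: int = 200,
    kmer_length: int = 30,
) -> MarkerDatabase:
    """Marker database for one community model (seeded from the model)."""
    return build_marker_db(
        model.genomes,
        markers_per_species=markers_per_species,
        marker_length=marker_length,
        kmer_length=kmer_length,
        seed=model.seed + 1,
    )
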