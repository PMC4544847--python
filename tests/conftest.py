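from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fmtdsi.synthetic_data import ReadRecord, SampleLibrary, make_community

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=length)]).decode()


def random_library(
    rng: np.random.Generator,
    n_reads: int,
    read_length: int = 60,
    sample_id: str = "S",
    source: SampleLibrary | None = None,
    copy_fraction: float = 0.0,
) -> SampleLibrary:
    """Random-read library; optionally copy a fraction of reads verbatim from
    ``source`` so the pair has a known-shared subset."""
    reads = []
    quality = chr(38 + 33) * read_length
    for i in range(n_reads):
        if source is not None and rng.random() < copy_fraction:
            seq = source.reads[rng.integers(0, len(source.reads))].sequence
        else:
            seq = random_sequence(rng, read_length)
        reads.append(ReadRecord(f"{sample_id}:r{i}", seq, chr(38 + 33) * len(seq)))
    return SampleLibrary(
        sample_id=sample_id, subject_id=sample_id, role="donor",
        timepoint_label="BL2", reads=reads,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def small_model():
    """10-species half-overlapping donor/recipient community, noise-free."""
    return make_community(10, overlap_fraction=0.5, seed=7, genome_length=5_000)
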