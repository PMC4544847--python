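"""FASTQ/FASTA/metadata readers and writers (Biopython-backed)."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .synthetic_data import ReadRecord, SampleLibrary

METADATA_COLUMNS = ["sample_id", "subject_id", "role", "donor_id", "timepoint"]


def write_fastq(library: SampleLibrary, path) -> None:
    """Write a library as 4-line Phred+33 FASTQ."""
    path = Path(path)
    with path.open("w") as fh:
        for read in library.reads:
            fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{read.quality}\n")


def read_fastq(
    path,
    *,
    sample_id: str,
    subject_id: str = "",
    role: str = "recipient",
    timepoint_label: str = "BL2",
) -> SampleLibrary:
    """Load a FASTQ file into a SampleLibrary (metadata supplied by caller)."""
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quality = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        reads.append(ReadRecord(rec.id, str(rec.seq).upper(), quality))
    return SampleLibrary(
        sample_id=sample_id,
        subject_id=subject_id,
        role=role,
        timepoint_label=timepoint_label,
        reads=reads,
    )


def write_fasta(records: list[tuple[str, str]], path) -> None:
    seq_records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(seq_records, str(path), "fasta")


def read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def read_metadata(path) -> pd.DataFrame:
    """Sample sheet TSV: sample_id, subject_id, role, donor_id, timepoint."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata is missing columns: {missing}")
    return df


def write_metadata(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
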