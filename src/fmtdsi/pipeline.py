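"""End-to-end orchestration: simulate -> QC -> similarity -> DSI -> taxonomy -> report.

The pipeline consumes a reads directory plus a sample sheet (TSV with
sample_id, subject_id, role, donor_id, timepoint), a host reference FASTA
and a marker FASTA, and writes deterministic TSV/JSON outputs: per-sample
QC, the DSI trajectory table, engraftment patterns and endpoint calls, the
recipient-vs-all-donors matrix, abundance and diversity tables, and the
species-level rule outputs. A sample flagged CNBP by QC is carried through
every table as an explicit CNBP marker and never silently dropped, and a
single failing sample never aborts the cohort.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _io
from .engraftment import (
    DSITrajectory,
    dsi_trajectory,
    endpoint_evaluation,
    pairwise_donor_matrix,
)
from .kmer_similarity import SimilarityConfig, build_index
from .sequence_qc import QCConfig, apply_qc, build_host_index
from .synthetic_data import (
    POST_TIMEPOINTS,
    TIMEPOINTS,
    CommunityModel,
    build_marker_db,
    generate_reads,
    make_community,
    mix_communities,
)
from .taxonomic_profiling import (
    AbundanceProfile,
    TaxonomyConfig,
    detect_large_changes,
    detect_transplanted_species,
    donor_recipient_species_test,
    profile_abundance,
    shannon_index,
)


@dataclass
class RunConfig:
    reads_dir: str
    metadata_path: str
    host_fasta: str
    marker_fasta: str
    out_dir: str
    qc: QCConfig = field(default_factory=QCConfig)
    similarity: SimilarityConfig = field(default_factory=SimilarityConfig)
    taxonomy: TaxonomyConfig = field(default_factory=TaxonomyConfig)
    seed: int = 0
    dsi_direction: str = "recipient_to_donor"
    declared_read_length: int | None = None

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def validate_config(config: RunConfig) -> list[str]:
    """Cross-field validation; returns a human-readable error list (empty = valid)."""
    errors: list[str] = []
    for name in ("reads_dir", "metadata_path", "host_fasta", "marker_fasta"):
        path = Path(getattr(config, name))
        if not path.exists():
            errors.append(f"{name}: {path} does not exist")
    if config.dsi_direction not in ("recipient_to_donor", "symmetric"):
        errors.append(f"dsi_direction: unknown value {config.dsi_direction!r}")
    if (
        config.declared_read_length is not None
        and config.similarity.k > config.declared_read_length
    ):
        errors.append(
            f"similarity k={config.similarity.k} exceeds declared read length "
            f"{config.declared_read_length}"
        )
    if Path(config.metadata_path).exists():
        try:
            meta = _io.read_metadata(config.metadata_path)
        except ValueError as exc:
            errors.append(str(exc))
        else:
            bad_tp = sorted(set(meta["timepoint"]) - set(TIMEPOINTS))
            if bad_tp:
                errors.append(f"unrecognized timepoint labels: {bad_tp}")
            if meta["sample_id"].duplicated().any():
                errors.append("duplicate sample_id entries in metadata")
            recipients = meta[meta["role"] == "recipient"]
            for subject, group in recipients.groupby("subject_id"):
                if "BL2" not in set(group["timepoint"]):
                    errors.append(f"recipient {subject} has no BL2 baseline sample")
    return errors


@dataclass
class RunReport:
    qc: pd.DataFrame
    trajectories: list[DSITrajectory]
    trajectory_table: pd.DataFrame
    endpoint: dict
    pairwise: object | None
    abundance: pd.DataFrame
    shannon: pd.DataFrame
    transplant_calls: pd.DataFrame
    large_changes: pd.DataFrame
    species_test: pd.DataFrame | None
    provenance: dict


def _trajectory_table(trajectories: list[DSITrajectory]) -> pd.DataFrame:
    """Engraftment-score rows: one row per recipient, columns per timepoint."""
    rows = []
    for traj in trajectories:
        row: dict[str, object] = {
            "recipient_id": traj.recipient_id,
            "donor_id": traj.donor_id,
            "S0": round(traj.s0, 4),
            "pattern": traj.pattern.value if traj.pattern else "",
        }
        for tp in traj.timepoints:
            row[tp.label] = "CNBP" if tp.cnbp else round(tp.dsi, 4)
        rows.append(row)
    cols = ["recipient_id", "donor_id", "S0", *POST_TIMEPOINTS, "pattern"]
    return pd.DataFrame(rows).reindex(columns=cols)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full analysis; deterministic given the config and inputs."""
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid run configuration:\n" + "\n".join(errors))

    meta = _io.read_metadata(config.metadata_path)
    reads_dir = Path(config.reads_dir)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    host_seqs = [seq for _, seq in _io.read_fasta(config.host_fasta)]
    host_index = build_host_index(host_seqs, config.qc.host_kmer_length)
    from .synthetic_data import MarkerDatabase

    marker_db = MarkerDatabase.from_fasta(config.marker_fasta, config.similarity.k)

    # --- QC every sample; CNBP samples stay in the tables as None libraries
    libraries: dict[str, object] = {}
    qc_rows = []
    for _, row in meta.iterrows():
        lib = _io.read_fastq(
            reads_dir / f"{row.sample_id}.fastq",
            sample_id=row.sample_id,
            subject_id=row.subject_id,
            role=row.role,
            timepoint_label=row.timepoint,
        )
        lib, report = apply_qc(lib, host_index, config.qc)
        qc_rows.append(report.to_dict())
        libraries[row.sample_id] = None if report.cnbp_flag else lib
    qc_table = pd.DataFrame(qc_rows)

    # --- group samples by subject/timepoint
    def _samples_of(subject: str) -> dict[str, object]:
        sub = meta[meta["subject_id"] == subject]
        return {row.timepoint: libraries[row.sample_id] for _, row in sub.iterrows()}

    recipients = sorted(meta.loc[meta["role"] == "recipient", "subject_id"].unique())
    donors = sorted(meta.loc[meta["role"] == "donor", "subject_id"].unique())
    pairing = {
        row.subject_id: row.donor_id
        for _, row in meta[meta["role"] == "recipient"].iterrows()
        if row.donor_id
    }
    donor_bl2 = {d: _samples_of(d).get("BL2") for d in donors}
    donor_indexes = {
        d: build_index(lib, config.similarity)
        for d, lib in donor_bl2.items()
        if lib is not None
    }

    # --- DSI trajectories
    trajectories: list[DSITrajectory] = []
    for rid in recipients:
        samples = _samples_of(rid)
        donor_id = pairing.get(rid)
        donor_lib = donor_bl2.get(donor_id)
        if donor_lib is None or samples.get("BL2") is None:
            continue  # trajectory undefined without both BL2 anchors
        trajectories.append(
            dsi_trajectory(
                samples,
                donor_lib,
                config.similarity,
                donor_index=donor_indexes[donor_id],
                direction=config.dsi_direction,
            )
        )
    trajectory_table = _trajectory_table(trajectories)
    per_recipient, endpoint_summary = endpoint_evaluation(trajectories)
    endpoint = {"per_recipient": per_recipient, **endpoint_summary}

    # --- recipient-vs-all-donors specificity matrix
    pairwise = None
    usable_donors = {d: lib for d, lib in donor_bl2.items() if lib is not None}
    if len(usable_donors) >= 2:
        pairwise = pairwise_donor_matrix(
            {rid: _samples_of(rid) for rid in recipients},
            usable_donors,
            pairing,
            config.similarity,
        )

    # --- taxonomy: profiles, diversity, rules
    profiles: dict[str, AbundanceProfile] = {}
    for sample_id, lib in libraries.items():
        if lib is not None:
            profiles[sample_id] = profile_abundance(lib, marker_db)
    sample_to_meta = meta.set_index("sample_id")
    abundance = (
        pd.DataFrame(
            {sid: prof.abundances for sid, prof in profiles.items()}
        )
        .fillna(0.0)
        .sort_index()
    )
    shannon_rows = [
        {
            "sample_id": sid,
            "subject_id": sample_to_meta.loc[sid, "subject_id"],
            "timepoint": sample_to_meta.loc[sid, "timepoint"],
            "shannon": shannon_index(prof) if prof.n_assigned_reads else float("nan"),
        }
        for sid, prof in profiles.items()
    ]
    shannon_table = pd.DataFrame(shannon_rows)

    def _profile_of(subject: str, label: str) -> AbundanceProfile | None:
        sub = meta[(meta["subject_id"] == subject) & (meta["timepoint"] == label)]
        if sub.empty:
            return None
        return profiles.get(sub.iloc[0]["sample_id"])

    call_rows = []
    change_frames = []
    for rid in recipients:
        donor_prof = _profile_of(pairing.get(rid, ""), "BL2")
        by_tp = {
            label: _profile_of(rid, label)
            for label in TIMEPOINTS
            if _profile_of(rid, label) is not None
        }
        if donor_prof is not None and {"BL1", "BL2"} <= set(by_tp):
            for call in detect_transplanted_species(
                by_tp, donor_prof, config.taxonomy, recipient_id=rid
            ):
                call_rows.append(
                    {
                        "recipient_id": rid,
                        "species": call.species,
                        "donor_abundance": call.donor_abundance,
                        "qualifies": call.qualifies,
                        "call": call.call or "",
                    }
                )
        pre = by_tp.get("BL2")
        for label in POST_TIMEPOINTS:
            post = by_tp.get(label)
            if pre is not None and post is not None:
                changes = detect_large_changes(pre, post, config.taxonomy)
                changes.insert(0, "recipient_id", rid)
                changes.insert(1, "timepoint", label)
                change_frames.append(changes)
    transplant_calls = pd.DataFrame(
        call_rows, columns=["recipient_id", "species", "donor_abundance", "qualifies", "call"]
    )
    large_changes = (
        pd.concat(change_frames, ignore_index=True) if change_frames else pd.DataFrame()
    )

    species_test = None
    donor_profs, recip_profs = [], []
    for rid in recipients:
        dp = _profile_of(pairing.get(rid, ""), "BL2")
        rp = _profile_of(rid, "BL2")
        if dp is not None and rp is not None:
            donor_profs.append(dp)
            recip_profs.append(rp)
    if len(donor_profs) >= 2:
        species_test = donor_recipient_species_test(
            donor_profs, recip_profs, config.taxonomy
        )

    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_samples": int(len(meta)),
        "n_cnbp": int(qc_table["cnbp_flag"].sum()),
    }
    report = RunReport(
        qc=qc_table,
        trajectories=trajectories,
        trajectory_table=trajectory_table,
        endpoint=endpoint,
        pairwise=pairwise,
        abundance=abundance,
        shannon=shannon_table,
        transplant_calls=transplant_calls,
        large_changes=large_changes,
        species_test=species_test,
        provenance=provenance,
    )
    _write_report(report, out_dir)
    return report


def _write_report(report: RunReport, out_dir: Path) -> None:
    report.qc.to_csv(out_dir / "qc_report.tsv", sep="\t", index=False)
    report.trajectory_table.to_csv(out_dir / "dsi_trajectories.tsv", sep="\t", index=False)
    report.abundance.to_csv(out_dir / "abundance.tsv", sep="\t")
    report.shannon.to_csv(out_dir / "shannon.tsv", sep="\t", index=False)
    report.transplant_calls.to_csv(out_dir / "transplant_calls.tsv", sep="\t", index=False)
    report.large_changes.to_csv(out_dir / "large_changes.tsv", sep="\t", index=False)
    if report.species_test is not None:
        report.species_test.to_csv(out_dir / "species_test.tsv", sep="\t", index=False)
    if report.pairwise is not None:
        report.pairwise.bl2.to_csv(out_dir / "pairwise_donor_bl2.tsv", sep="\t")
        report.pairwise.wk1.to_csv(out_dir / "pairwise_donor_wk1.tsv", sep="\t")
    summary = {
        "endpoint": report.endpoint,
        "patterns": {
            t.recipient_id: (t.pattern.value if t.pattern else None)
            for t in report.trajectories
        },
        "specificity": report.pairwise.specific if report.pairwise else None,
        "provenance": report.provenance,
    }
    (out_dir / "run_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# demo cohort


def make_demo(
    seed: int = 0,
    out_dir: str | Path = "demo",
    *,
    n_pairs: int = 3,
    n_species: int = 20,
    genome_length: int = 8_000,
    reads_per_sample: int = 2_000,
    read_length: int = 93,
    overlap_fraction: float = 0.3,
    host_fraction: float = 0.02,
    error_rate: float = 0.002,
    duplicate_fraction: float = 0.02,
    schedules: list[dict[str, float]] | None = None,
    cnbp_subject: str | None = None,
) -> Path:
    """Write a self-contained synthetic cohort (FASTQ + metadata + references).

    Each donor/recipient pair gets its own community; all species pools are
    pooled into one marker database and all samples share one synthetic
    host reference. ``cnbp_subject`` optionally injects ~95% host reads
    into that recipient's WK1 sample so the depth gate trips downstream.
    Returns the bundle directory; a ``truth.json`` sidecar records the
    engraftment schedules and per-sample ground truth counts.
    """
    out_dir = Path(out_dir)
    (out_dir / "fastq").mkdir(parents=True, exist_ok=True)
    if schedules is None:
        schedules = [
            {"WK1": 0.5, "MO1": 0.4, "MO2_3": 0.1},  # moderate rise then decline
            {"WK1": 0.1, "MO1": 0.2, "MO2_3": 0.35},  # low then gradual rise
            {"WK1": 0.6, "MO1": 0.3, "MO2_3": 0.05},
        ]
    rng = np.random.default_rng(seed)
    models: list[CommunityModel] = []
    meta_rows = []
    truth: dict[str, object] = {"seed": seed, "pairs": {}, "samples": {}}

    host_model = make_community(2, seed=seed + 101)  # source of the shared host sequence
    host_sequence = host_model.host_sequence

    genomes_all: dict[str, str] = {}
    for p in range(n_pairs):
        model = make_community(
            n_species,
            overlap_fraction=overlap_fraction,
            genome_length=genome_length,
            seed=int(rng.integers(0, 2**31 - 1)),
            engraftment_schedule=schedules[p % len(schedules)],
            host_fraction=host_fraction,
            error_rate=error_rate,
            duplicate_fraction=duplicate_fraction,
            species_prefix=f"p{p + 1}_sp",
        )
        model.host_sequence = host_sequence
        models.append(model)
        genomes_all.update(model.genomes)
        truth["pairs"][f"pair{p + 1}"] = {
            "engraftment_schedule": model.engraftment_schedule,
            "species_ids": model.species_ids,
        }

    marker_db = build_marker_db(genomes_all, seed=seed + 7)
    marker_db.to_fasta(out_dir / "markers.fasta")
    _io.write_fasta([("host", host_sequence)], out_dir / "host.fasta")

    for p, model in enumerate(models):
        rid, did = f"R{p + 1}", f"D{p + 1}"
        plan: list[tuple[str, str, str, np.ndarray, float]] = [
            (did, "donor", "BL2", model.donor_abundance, model.host_fraction),
            (rid, "recipient", "BL1", model.recipient_abundance, model.host_fraction),
            (rid, "recipient", "BL2", model.recipient_abundance, model.host_fraction),
        ]
        for label in POST_TIMEPOINTS:
            hf = model.host_fraction
            if cnbp_subject == rid and label == "WK1":
                hf = 0.95
            plan.append((rid, "recipient", label, mix_communities(model, label), hf))
        for subject, role, label, abundance, hf in plan:
            sample_id = f"{subject}_{label}"
            saved_hf = model.host_fraction
            model.host_fraction = hf
            library, sample_truth = generate_reads(
                model,
                abundance,
                reads_per_sample,
                read_length,
                sample_id=sample_id,
                subject_id=subject,
                role=role,
                timepoint_label=label,
            )
            model.host_fraction = saved_hf
            _io.write_fastq(library, out_dir / "fastq" / f"{sample_id}.fastq")
            truth["samples"][sample_id] = {
                "expected_qc": sample_truth["expected_qc"],
                "n_host": len(sample_truth["host_read_ids"]),
                "n_injected_duplicates": len(sample_truth["injected_duplicate_ids"]),
            }
            meta_rows.append(
                {
                    "sample_id": sample_id,
                    "subject_id": subject,
                    "role": role,
                    "donor_id": did if role == "recipient" else "",
                    "timepoint": label,
                }
            )

    _io.write_metadata(pd.DataFrame(meta_rows), out_dir / "metadata.tsv")
    (out_dir / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    return out_dir


def demo_run_config(bundle_dir: str | Path, out_dir: str | Path, seed: int = 0) -> RunConfig:
    """RunConfig for a bundle written by :func:`make_demo` (desk-scale depth gate)."""
    bundle_dir = Path(bundle_dir)
    return RunConfig(
        reads_dir=str(bundle_dir / "fastq"),
        metadata_path=str(bundle_dir / "metadata.tsv"),
        host_fasta=str(bundle_dir / "host.fasta"),
        marker_fasta=str(bundle_dir / "markers.fasta"),
        out_dir=str(out_dir),
        qc=QCConfig(min_reads_after_filtering=500),
        seed=seed,
    )
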