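"""Donor Similarity Index (DSI) and engraftment-trajectory analysis.

The DSI rescales recipient-to-donor similarity so that the pre-transplant
baseline maps to 0 and perfect donor similarity maps to 100:

    DSI = 100 * (S_t - S_0) / (100 - S_0)

where S_0 is the recipient's similarity to the donor immediately before
transplant (the BL2 sample) and S_t the similarity at a post-transplant
timepoint. The index is the percentage of the headroom between baseline
and perfect engraftment that has been closed at time t; it is negative
when the recipient has drifted away from the donor and is deliberately
not clamped.

Samples that failed QC (CNBP, "could not be performed") propagate as
missing values, never as zeros.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .kmer_similarity import KmerIndex, SimilarityConfig, build_index, similarity
from .synthetic_data import POST_TIMEPOINTS, SampleLibrary


class Pattern(enum.Enum):
    MODERATE_RISE_THEN_DECLINE = "moderate_rise_then_decline"
    LOW_THEN_GRADUAL_RISE = "low_then_gradual_rise"
    INDETERMINATE = "indeterminate"


def compute_dsi(s0: float, st: float) -> float:
    """Donor Similarity Index for baseline similarity ``s0`` and current ``st``.

    Both arguments are percentages in [0, 100]; ``s0`` must be strictly
    below 100 (at 100 the index is undefined — there is no headroom left).
    """
    if not 0.0 <= s0 <= 100.0 or not 0.0 <= st <= 100.0:
        raise ValueError(f"similarities must lie in [0, 100]: S0={s0}, St={st}")
    if s0 == 100.0:
        raise ZeroDivisionError("DSI undefined at S0=100 (degenerate baseline)")
    return 100.0 * (st - s0) / (100.0 - s0)


@dataclass
class TimepointDSI:
    label: str
    similarity: float | None  # recipient-to-donor S_t, percent; None if CNBP
    dsi: float | None
    cnbp: bool = False
    self_similarity: float | None = None  # recipient-to-own-baseline, percent


@dataclass
class DSITrajectory:
    """Per-recipient DSI time course against the paired donor's BL2 sample."""

    recipient_id: str
    donor_id: str
    s0: float
    timepoints: list[TimepointDSI] = field(default_factory=list)
    pattern: Pattern | None = None
    baseline_drift: float | None = None  # similarity of recipient BL1 to BL2

    def dsi_values(self) -> list[float | None]:
        return [tp.dsi for tp in self.timepoints]


def dsi_trajectory(
    recipient_samples: Mapping[str, SampleLibrary | None],
    donor_bl2_sample: SampleLibrary,
    similarity_config: SimilarityConfig | None = None,
    *,
    donor_index: KmerIndex | None = None,
    direction: str = "recipient_to_donor",
) -> DSITrajectory:
    """Compute S0 from the recipient's BL2 sample, then DSI per post timepoint.

    ``recipient_samples`` maps timepoint labels to libraries; a None value
    marks a CNBP sample. BL2 is mandatory and must be non-CNBP (otherwise
    the whole trajectory is undefined). If BL1 is present, the BL1-vs-BL2
    similarity is recorded as a baseline-drift control. ``direction``
    selects the recipient-to-donor percentage (default) or the symmetric
    score for S.
    """
    config = similarity_config or SimilarityConfig()
    if direction not in ("recipient_to_donor", "symmetric"):
        raise ValueError(f"unknown DSI direction {direction!r}")
    bl2 = recipient_samples.get("BL2")
    if bl2 is None:
        raise ValueError("recipient BL2 sample missing or CNBP; trajectory undefined")

    donor_index = donor_index or build_index(donor_bl2_sample, config)
    bl2_index = build_index(bl2, config)

    def _s(sample: SampleLibrary) -> float:
        res = similarity(sample, donor_bl2_sample, config, target_index=donor_index)
        return res.pct_query_in_target if direction == "recipient_to_donor" else res.symmetric_pct

    s0 = _s(bl2)

    drift = None
    bl1 = recipient_samples.get("BL1")
    if bl1 is not None:
        drift = similarity(bl1, bl2, config, target_index=bl2_index).pct_query_in_target

    timepoints: list[TimepointDSI] = []
    for label in POST_TIMEPOINTS:
        if label not in recipient_samples:
            continue
        sample = recipient_samples[label]
        if sample is None:
            timepoints.append(TimepointDSI(label, None, None, cnbp=True))
            continue
        st = _s(sample)
        self_sim = similarity(sample, bl2, config, target_index=bl2_index).pct_query_in_target
        timepoints.append(
            TimepointDSI(label, st, compute_dsi(s0, st), self_similarity=self_sim)
        )

    traj = DSITrajectory(
        recipient_id=bl2.subject_id or bl2.sample_id,
        donor_id=donor_bl2_sample.subject_id or donor_bl2_sample.sample_id,
        s0=s0,
        timepoints=timepoints,
        baseline_drift=drift,
    )
    try:
        traj.pattern = classify_pattern(traj)
    except ValueError:
        traj.pattern = Pattern.INDETERMINATE
    return traj


def classify_pattern(
    trajectory: DSITrajectory | Sequence[float | None],
    rise_threshold: float = 40.0,
    late_drop_fraction: float = 0.0,
) -> Pattern:
    """Classify a DSI time course into the two observed engraftment patterns.

    Given the post-transplant DSI sequence (1 week first; None marks CNBP):
    a *moderate rise then decline* is an initial DSI at or above
    ``rise_threshold`` followed by a final DSI below the initial one (by
    more than ``late_drop_fraction`` of it); a *low then gradual rise* is an
    initial DSI below the threshold with a final DSI above it. Anything
    else — including trajectories with fewer than two usable points —
    is indeterminate.

    This is a formalization of an observed dichotomy, not a canonical rule;
    the threshold default of 40 follows the reported cut between "moderate" (>40%) and "low" initial engraftment.
    """
    if isinstance(trajectory, DSITrajectory):
        values: list[float | None] = trajectory.dsi_values()
    else:
        values = list(trajectory)
    usable = [v for v in values if v is not None]
    if len(usable) < 2 or not values or values[0] is None:
        return Pattern.INDETERMINATE
    first = values[0]
    last = usable[-1]
    if first >= rise_threshold and last < first * (1.0 - late_drop_fraction):
        return Pattern.MODERATE_RISE_THEN_DECLINE
    if first < rise_threshold and last > first:
        return Pattern.LOW_THEN_GRADUAL_RISE
    return Pattern.INDETERMINATE


@dataclass
class PairwiseDonorMatrix:
    """Recipient (BL2, WK1) similarity to every donor's BL2 sample.

    ``specific`` records, per recipient, whether the 1-week similarity gain
    toward the *own* donor strictly exceeds the gain toward every other
    donor (None when WK1 or the own-donor column is unavailable).
    """

    bl2: pd.DataFrame  # recipients x donors, percent
    wk1: pd.DataFrame
    own_donor: dict[str, str]
    specific: dict[str, bool | None]


def pairwise_donor_matrix(
    all_recipients: Mapping[str, Mapping[str, SampleLibrary | None]],
    all_donors: Mapping[str, SampleLibrary],
    pairing: Mapping[str, str],
    similarity_config: SimilarityConfig | None = None,
) -> PairwiseDonorMatrix:
    """Compare every recipient's BL2 and WK1 samples against all donors.

    ``all_recipients`` maps recipient id -> {timepoint label -> library};
    ``all_donors`` maps donor id -> BL2 library; ``pairing`` maps each
    recipient to its own donor. Two recipients may share a donor column.
    """
    config = similarity_config or SimilarityConfig()
    if len(all_donors) < 2:
        raise ValueError("pairwise specificity needs at least 2 donors")
    donor_ids = list(all_donors)
    donor_indexes = {did: build_index(lib, config) for did, lib in all_donors.items()}

    rows_bl2: dict[str, dict[str, float]] = {}
    rows_wk1: dict[str, dict[str, float]] = {}
    for rid, samples in all_recipients.items():
        for label, rows in (("BL2", rows_bl2), ("WK1", rows_wk1)):
            sample = samples.get(label)
            if sample is None:
                continue
            rows[rid] = {
                did: similarity(
                    sample, all_donors[did], config, target_index=donor_indexes[did]
                ).pct_query_in_target
                for did in donor_ids
            }

    bl2 = pd.DataFrame.from_dict(rows_bl2, orient="index").reindex(columns=donor_ids)
    wk1 = pd.DataFrame.from_dict(rows_wk1, orient="index").reindex(columns=donor_ids)

    specific: dict[str, bool | None] = {}
    for rid in all_recipients:
        own = pairing.get(rid)
        if own is None or rid not in rows_bl2 or rid not in rows_wk1:
            specific[rid] = None
            continue
        gains = {did: rows_wk1[rid][did] - rows_bl2[rid][did] for did in donor_ids}
        own_gain = gains.pop(own)
        specific[rid] = bool(gains) and all(own_gain > g for g in gains.values())
    return PairwiseDonorMatrix(bl2=bl2, wk1=wk1, own_donor=dict(pairing), specific=specific)


def endpoint_evaluation(
    trajectories: Sequence[DSITrajectory],
    threshold: float = 50.0,
    timepoint_label: str = "MO1",
) -> tuple[dict[str, bool | None], dict[str, int]]:
    """Per-recipient engraftment endpoint: DSI > threshold at a timepoint.

    CNBP (or absent) timepoints are not evaluable and map to None. Returns
    the per-recipient booleans and a cohort summary with the number of
    recipients, evaluable recipients, and passes.
    """
    if timepoint_label not in POST_TIMEPOINTS:
        raise ValueError(f"unknown post-transplant timepoint {timepoint_label!r}")
    per_recipient: dict[str, bool | None] = {}
    for traj in trajectories:
        value = next(
            (tp.dsi for tp in traj.timepoints if tp.label == timepoint_label), None
        )
        per_recipient[traj.recipient_id] = None if value is None else value > threshold
    evaluable = [v for v in per_recipient.values() if v is not None]
    summary = {
        "n_recipients": len(per_recipient),
        "n_evaluable": len(evaluable),
        "n_passing": sum(evaluable),
    }
    return per_recipient, summary
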