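"""DSI arithmetic, trajectory patterns, endpoint logic, donor specificity."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fmtdsi.engraftment import (
    DSITrajectory,
    Pattern,
    TimepointDSI,
    classify_pattern,
    compute_dsi,
    dsi_trajectory,
    endpoint_evaluation,
    pairwise_donor_matrix,
)
from fmtdsi.kmer_similarity import SimilarityConfig
from fmtdsi.synthetic_data import generate_reads, make_community, mix_communities


@pytest.mark.parametrize(
    "s0,st,expected",
    [
        (25.0, 25.0, 0.0),  # no change from baseline
        (40.0, 100.0, 100.0),  # perfect engraftment
        (50.0, 60.0, 20.0),
        (50.0, 40.0, -20.0),  # drift away from donor is negative
        (0.0, 50.0, 50.0),
    ],
)
def test_compute_dsi_values(s0, st, expected):
    assert compute_dsi(s0, st) == pytest.approx(expected)


def test_compute_dsi_domain_errors():
    with pytest.raises(ZeroDivisionError):
        compute_dsi(100.0, 50.0)
    for s0, st in [(-1, 50), (101, 50), (50, -1), (50, 101)]:
        with pytest.raises(ValueError):
            compute_dsi(s0, st)


@given(
    s0=st.floats(min_value=0, max_value=99.5),
    dsi=st.floats(min_value=-100, max_value=100),
)
def test_dsi_headroom_roundtrip(s0, dsi):
    """DSI is the percent of remaining headroom closed: St = S0 + DSI*(100-S0)/100
    recovers the same DSI."""
    st_val = s0 + dsi * (100.0 - s0) / 100.0
    if 0.0 <= st_val <= 100.0:
        assert compute_dsi(s0, st_val) == pytest.approx(dsi, abs=1e-9)


def test_dsi_strictly_increasing_in_st():
    values = [compute_dsi(30.0, st_val) for st_val in np.linspace(0, 100, 21)]
    assert all(b > a for a, b in zip(values, values[1:]))


# engraftment-score rows observed in a six-recipient FMT cohort (1 Wk, 1 Mo, 2-3 Mo; None = CNBP)
COHORT_TRAJECTORIES = {
    "R1": [3.4, None, 13.0],
    "R2": [3.5, None, None],
    "R3": [43.1, 47.9, -4.7],
    "R5": [52.9, 41.1, 19.5],
    "R6": [43.1, 21.1, 12.3],
    "R7": [1.5, 18.2, 24.9],
}


def test_pattern_classification_of_cohort_trajectories():
    patterns = {rid: classify_pattern(vals) for rid, vals in COHORT_TRAJECTORIES.items()}
    assert {r for r, p in patterns.items() if p is Pattern.MODERATE_RISE_THEN_DECLINE} == {
        "R3", "R5", "R6",
    }
    assert {r for r, p in patterns.items() if p is Pattern.LOW_THEN_GRADUAL_RISE} == {
        "R1", "R7",
    }
    assert patterns["R2"] is Pattern.INDETERMINATE


def test_pattern_requires_two_usable_points():
    assert classify_pattern([50.0]) is Pattern.INDETERMINATE
    assert classify_pattern([None, 10.0, 20.0]) is Pattern.INDETERMINATE


def _cohort_as_trajectories():
    labels = ("WK1", "MO1", "MO2_3")
    trajs = []
    for rid, vals in COHORT_TRAJECTORIES.items():
        tps = [
            TimepointDSI(label, None if v is None else 0.0, v, cnbp=v is None)
            for label, v in zip(labels, vals)
        ]
        trajs.append(DSITrajectory(recipient_id=rid, donor_id="D", s0=0.0, timepoints=tps))
    return trajs


def test_endpoint_counts_at_one_month():
    trajs = _cohort_as_trajectories()
    _, at50 = endpoint_evaluation(trajs, threshold=50.0, timepoint_label="MO1")
    assert at50["n_evaluable"] == 4
    assert at50["n_passing"] == 0
    per, at40 = endpoint_evaluation(trajs, threshold=40.0, timepoint_label="MO1")
    assert at40["n_passing"] == 2
    assert per["R3"] and per["R5"]
    assert per["R1"] is None and per["R2"] is None  # CNBP -> not evaluable

    with pytest.raises(ValueError):
        endpoint_evaluation(trajs, timepoint_label="BL9")


@pytest.fixture(scope="module")
def engraftment_cohort():
    """Disjoint donor/recipient communities with a declining engraftment schedule."""
    model = make_community(
        12, overlap_fraction=0.0, seed=21, genome_length=8_000,
        engraftment_schedule={"WK1": 0.6, "MO1": 0.4, "MO2_3": 0.1},
    )
    n = 4_000

    def lib(abundance, sample_id, subject, role, label):
        library, _ = generate_reads(
            model, abundance, n, sample_id=sample_id,
            subject_id=subject, role=role, timepoint_label=label,
        )
        return library

    donor = lib(model.donor_abundance, "D_BL2", "D", "donor", "BL2")
    samples = {
        "BL1": lib(model.recipient_abundance, "R_BL1", "R", "recipient", "BL1"),
        "BL2": lib(model.recipient_abundance, "R_BL2", "R", "recipient", "BL2"),
    }
    for label in ("WK1", "MO1", "MO2_3"):
        samples[label] = lib(
            mix_communities(model, label), f"R_{label}", "R", "recipient", label
        )
    return model, donor, samples


def test_trajectory_tracks_declining_engraftment(engraftment_cohort):
    model, donor, samples = engraftment_cohort
    traj = dsi_trajectory(samples, donor)
    dsis = traj.dsi_values()
    assert traj.s0 == pytest.approx(0.0, abs=2.0)  # disjoint communities
    # DSI strictly decreasing along the declining pi schedule
    assert dsis[0] > dsis[1] > dsis[2]
    # and near the mixing fractions themselves
    for dsi, pi in zip(dsis, (0.6, 0.4, 0.1)):
        assert dsi == pytest.approx(100 * pi, abs=8.0)
    assert traj.baseline_drift is not None and traj.baseline_drift > 90.0


def test_trajectory_cnbp_entries_do_not_affect_others(engraftment_cohort):
    _, donor, samples = engraftment_cohort
    with_cnbp = dict(samples)
    with_cnbp["MO1"] = None  # QC-failed sample
    traj = dsi_trajectory(with_cnbp, donor)
    by_label = {tp.label: tp for tp in traj.timepoints}
    assert by_label["MO1"].cnbp and by_label["MO1"].dsi is None
    full = dsi_trajectory(samples, donor)
    assert by_label["WK1"].dsi == pytest.approx(
        {tp.label: tp for tp in full.timepoints}["WK1"].dsi
    )


def test_trajectory_requires_bl2(engraftment_cohort):
    _, donor, samples = engraftment_cohort
    no_bl2 = {k: v for k, v in samples.items() if k != "BL2"}
    with pytest.raises(ValueError):
        dsi_trajectory(no_bl2, donor)


def test_pairwise_specificity_on_disjoint_cohort():
    """Recipients mixed 50/50 with their own donor gain most toward that donor;
    an unmixed recipient shows no specific gain."""
    config = SimilarityConfig()
    recipients, donors, pairing = {}, {}, {}
    pis = {"R1": 0.5, "R2": 0.5, "R3": 0.0}
    for i, (rid, pi) in enumerate(pis.items(), start=1):
        model = make_community(
            10, overlap_fraction=0.0, seed=100 + i, genome_length=8_000,
            engraftment_schedule={"WK1": pi},
        )
        did = f"D{i}"
        donors[did], _ = generate_reads(
            model, model.donor_abundance, 2_000,
            sample_id=f"{did}_BL2", subject_id=did, role="donor", timepoint_label="BL2",
        )
        bl2, _ = generate_reads(
            model, model.recipient_abundance, 2_000,
            sample_id=f"{rid}_BL2", subject_id=rid, timepoint_label="BL2",
        )
        wk1, _ = generate_reads(
            model, mix_communities(model, "WK1"), 2_000,
            sample_id=f"{rid}_WK1", subject_id=rid, timepoint_label="WK1",
        )
        recipients[rid] = {"BL2": bl2, "WK1": wk1}
        pairing[rid] = did
    matrix = pairwise_donor_matrix(recipients, donors, pairing, config)
    assert matrix.specific["R1"] is True
    assert matrix.specific["R2"] is True
    assert matrix.specific["R3"] is False
    assert ((matrix.bl2.to_numpy() >= 0) & (matrix.bl2.to_numpy() <= 100)).all()


def test_pairwise_needs_two_donors(rng):
    with pytest.raises(ValueError):
        pairwise_donor_matrix({}, {"D1": None}, {})
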