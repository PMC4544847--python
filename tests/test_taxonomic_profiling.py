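"""Marker profiling, Shannon diversity, species rules, paired test + FDR."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import oracles
from fmtdsi.synthetic_data import generate_reads, make_community, make_marker_db
from fmtdsi.taxonomic_profiling import (
    AbundanceProfile,
    TaxonomyConfig,
    benjamini_hochberg,
    detect_large_changes,
    detect_transplanted_species,
    donor_recipient_species_test,
    profile_abundance,
    shannon_index,
)


def _profile(sample_id="S", **abundances):
    return AbundanceProfile(
        sample_id=sample_id, abundances=dict(abundances),
        n_assigned_reads=1000 if abundances else 0,
    )


@pytest.fixture(scope="module")
def profiled_pair():
    model = make_community(6, overlap_fraction=1.0, seed=31, genome_length=5_000)
    db = make_marker_db(model, markers_per_species=4, marker_length=150)
    return model, db


def test_single_species_profiles_to_100(profiled_pair):
    model, db = profiled_pair
    abundance = np.zeros(6)
    abundance[0] = 100.0
    lib, _ = generate_reads(model, abundance, 400, sample_id="mono")
    prof = profile_abundance(lib, db)
    assert prof.abundances == {model.species_ids[0]: 100.0}
    assert prof.n_assigned_reads > 0


def test_even_mixture_recovered_within_binomial_error(profiled_pair):
    model, db = profiled_pair
    abundance = np.zeros(6)
    abundance[0] = abundance[1] = 50.0
    lib, _ = generate_reads(model, abundance, 2_000, sample_id="even")
    prof = profile_abundance(lib, db)
    n = prof.n_assigned_reads
    lo, hi = stats.binom.interval(0.9999, n, 0.5)
    assert lo / n * 100 <= prof.abundances[model.species_ids[0]] <= hi / n * 100
    assert abs(sum(prof.abundances.values()) - 100.0) < 1e-6


def test_profiler_kmer_longer_than_marker_rejected(profiled_pair):
    model, db = profiled_pair
    lib, _ = generate_reads(model, model.donor_abundance, 10, sample_id="tiny")
    with pytest.raises(ValueError):
        profile_abundance(lib, db, kmer_length=db.marker_length + 1)


@pytest.mark.parametrize(
    "abundances,expected",
    [
        ({"a": 100.0}, 0.0),
        ({"a": 25.0, "b": 25.0, "c": 25.0, "d": 25.0}, math.log(4)),
        ({"a": 50.0, "b": 25.0, "c": 25.0}, 1.0397207708399179),
    ],
)
def test_shannon_closed_forms(abundances, expected):
    assert shannon_index(_profile(**abundances)) == pytest.approx(expected, abs=1e-9)


def test_shannon_empty_profile_raises():
    with pytest.raises(ValueError):
        shannon_index(_profile())


def test_shannon_max_for_uniform_profile():
    for s in (2, 5, 17):
        uniform = {f"sp{i}": 100.0 / s for i in range(s)}
        assert shannon_index(_profile(**uniform)) == pytest.approx(math.log(s))


def _timepoint_profiles(post_wk1=0.5, post_mo1=0.0, post_mo23=0.0, baseline=0.0):
    filler = lambda x: {"resident": 100.0 - x}
    return {
        "BL1": _profile(species=baseline, **filler(baseline)),
        "BL2": _profile(species=baseline, **filler(baseline)),
        "WK1": _profile(species=post_wk1, **filler(post_wk1)),
        "MO1": _profile(species=post_mo1, **filler(post_mo1)),
        "MO2_3": _profile(species=post_mo23, **filler(post_mo23)),
    }


def test_transplant_rule_threshold_and_subtypes():
    donor = _profile(species=3.0, resident=97.0)
    calls = detect_transplanted_species(_timepoint_profiles(post_wk1=0.5), donor)
    call = next(c for c in calls if c.species == "species")
    assert call.qualifies and call.call == "transient"

    below = detect_transplanted_species(_timepoint_profiles(post_wk1=0.1), donor)
    assert not next(c for c in below if c.species == "species").qualifies

    persistent = detect_transplanted_species(
        _timepoint_profiles(post_wk1=0.5, post_mo1=0.4, post_mo23=0.3), donor
    )
    assert next(c for c in persistent if c.species == "species").call == "persistent"

    late = detect_transplanted_species(
        _timepoint_profiles(post_wk1=0.0, post_mo1=0.4), donor
    )
    assert next(c for c in late if c.species == "species").call == "late"


def test_transplant_rule_requires_undetectable_baselines():
    donor = _profile(species=3.0, resident=97.0)
    detected_at_baseline = detect_transplanted_species(
        _timepoint_profiles(post_wk1=0.5, baseline=0.3), donor
    )
    assert not next(c for c in detected_at_baseline if c.species == "species").qualifies
    with pytest.raises(ValueError):
        detect_transplanted_species({"BL2": _profile(a=100.0)}, donor)


def test_transplanted_species_recovered_exactly_on_synthetic_cohort():
    """Five donor-only species above the post-mix threshold are all recovered,
    with no false calls among recipient-resident species."""
    model = make_community(
        10, overlap_fraction=0.0, seed=41, genome_length=5_000,
        engraftment_schedule={"WK1": 0.5},
    )
    db = make_marker_db(model, markers_per_species=4, marker_length=150)
    donor_support = np.nonzero(model.donor_abundance)[0]
    assert len(donor_support) == 5

    def prof(abundance, sid):
        lib, _ = generate_reads(model, abundance, 4_000, sample_id=sid)
        return profile_abundance(lib, db)

    mix = 0.5 * model.recipient_abundance + 0.5 * model.donor_abundance
    profiles = {
        "BL1": prof(model.recipient_abundance, "bl1"),
        "BL2": prof(model.recipient_abundance, "bl2"),
        "WK1": prof(mix, "wk1"),
    }
    donor_profile = prof(model.donor_abundance, "donor")
    calls = detect_transplanted_species(profiles, donor_profile)
    qualifying = {c.species for c in calls if c.qualifies}
    assert qualifying == {model.species_ids[i] for i in donor_support}


def test_large_change_arithmetic_and_flags():
    pre = _profile(a=0.01, b=5.0, c=2.0, d=1.0, filler=91.99)
    post = _profile(a=1.0, b=80.0, c=2.0, e=16.99, filler=0.01)
    changes = detect_large_changes(pre, post).set_index("species")
    assert changes.loc["a", "log_change"] == pytest.approx(2.0)
    assert changes.loc["a", "abs_change"] == pytest.approx(0.99)
    assert bool(changes.loc["a", "log_flag"]) and not bool(changes.loc["a", "large_abs"])
    assert changes.loc["b", "abs_change"] == pytest.approx(75.0)
    assert bool(changes.loc["b", "large_abs"]) and bool(changes.loc["b", "log_flag"])
    assert not bool(changes.loc["c", "log_flag"]) and not bool(changes.loc["c", "large_abs"])
    assert bool(changes.loc["d", "to_zero"]) and bool(changes.loc["e", "from_zero"])


def test_identical_profiles_produce_no_flags():
    p = _profile(a=60.0, b=40.0)
    changes = detect_large_changes(p, p)
    assert not changes["large_abs"].any() and not changes["log_flag"].any()


def test_bh_worked_example():
    q = benjamini_hochberg([0.01, 0.02, 0.03, 0.5])
    np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.5])


@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
def test_bh_matches_brute_force(pvals):
    np.testing.assert_allclose(benjamini_hochberg(pvals), oracles.oracle_bh(pvals), atol=1e-12)


def test_paired_test_degenerate_and_enriched_species():
    identical = [_profile(a=60.0, b=40.0) for _ in range(3)]
    df = donor_recipient_species_test(identical, identical).set_index("species")
    assert (df["p"] == 1.0).all()
    assert not df["significant"].any()

    rng = np.random.default_rng(5)
    donors, recips = [], []
    for _ in range(6):
        base = np.abs(rng.normal(10, 1, size=5))
        d = base.copy()
        d[0] += 15.0  # strong consistent donor enrichment in species s0
        donors.append(_vec_profile(d))
        recips.append(_vec_profile(base + rng.normal(0, 0.5, size=5)))
    result = donor_recipient_species_test(donors, recips)
    best = result.sort_values("p").iloc[0]
    assert best["species"] == "s0"
    assert best["mean_donor"] > best["mean_recipient"]


def _vec_profile(values):
    values = 100.0 * np.asarray(values) / np.sum(values)
    return AbundanceProfile(
        sample_id="S",
        abundances={f"s{i}": v for i, v in enumerate(values)},
        n_assigned_reads=1000,
    )


def test_paired_test_needs_two_pairs():
    with pytest.raises(ValueError):
        donor_recipient_species_test([_profile(a=100.0)], [_profile(a=100.0)])


def test_type_i_error_controlled_under_null():
    """Simulated null cohorts (donor and recipient drawn from the same
    distribution) should yield essentially no FDR-significant species."""
    rng = np.random.default_rng(17)
    n_species, n_pairs, n_cohorts = 30, 7, 20
    total_tests = total_significant = 0
    for _ in range(n_cohorts):
        donors = [_vec_profile(rng.lognormal(0, 1, n_species)) for _ in range(n_pairs)]
        recips = [_vec_profile(rng.lognormal(0, 1, n_species)) for _ in range(n_pairs)]
        df = donor_recipient_species_test(donors, recips)
        total_tests += len(df)
        total_significant += int(df["significant"].sum())
    assert total_significant / total_tests <= 0.05
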